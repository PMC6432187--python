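"""Phase-diagram orchestration: per-stiffness multicanonical analysis.

For each bending stiffness kappa the pipeline is: hot canonical pilot run
(upper energy bound) -> multicanonical weight iteration covering the
temperature window -> flat-histogram production -> (a) canonical curves
CV(T), dRgyr^2/dT, dGamma2/dT by reweighting, with transition points from
their peaks, and (b) microcanonical profile beta(Ep), gamma(Ep) with the
finite-size transition-order call from the gamma-peak sign.

The sign of the dominant gamma peak along the collapse line flips from
negative (second-order-like, flexible chains) to positive (first-order-like
folding, stiff chains); :func:`find_gamma_crossover` brackets the stiffness
where that happens by sign bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import initial_conformation
from .microcanonical import (DensityOfStates, MicroProfile, TransitionCall,
                             classify_transition, dos_from_weights,
                             micro_beta_gamma)
from .models import Conformation, ModelSpec, total_energy
from .reweighting import TaggedSeries, canonical_curve, scan_peaks
from .sampling import (HistogramRecord, WeightTable, _sub_seeds,
                       iterate_muca_weights, muca_production, run_canonical)


def pilot_energy_range(conf: Conformation, spec: ModelSpec, t_hot: float,
                       *, seed: int = 0, sweeps: int = 4000,
                       margin: float = 5.0) -> float:
    """Upper energy bound from a short canonical run at the hot end."""
    res = run_canonical(conf, spec, t_hot, sweeps,
                        discard=sweeps // 4, seed=seed)
    return float(res.col("ep").max() + margin)


def _contiguous_block(mask: np.ndarray) -> slice:
    """Longest contiguous True run of a boolean mask."""
    best = (0, 0)
    start = None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return slice(*best)


@dataclass
class MicroAnalysis:
    dos: DensityOfStates
    profile: MicroProfile
    call: TransitionCall
    gamma_extremum: float      # signed gamma at the largest-|gamma| point
    e_extremum: float


def micro_analysis(weights: WeightTable, hist: HistogramRecord, *,
                   smoothing: float = 4.0, min_count: int = 20,
                   trim: int | None = None,
                   e_window: tuple[float, float] | None = None
                   ) -> MicroAnalysis:
    """Microcanonical profile restricted to the well-sampled energy block.

    Bins with fewer than ``min_count`` production visits are excluded, and
    the block edges are trimmed (default: 8% of the block length, at least
    4 bins) before classification -- finite differences and Gaussian
    smoothing are unreliable at the boundaries of the sampled range.
    ``e_window`` further restricts the gamma-extremum search to a known
    transition region (e.g. around the canonical specific-heat peak),
    which suppresses spurious extrema from poorly sampled tails.
    """
    block = _contiguous_block(hist.counts >= min_count)
    if trim is None:
        trim = max(4, int(0.08 * (block.stop - block.start)))
    sub_hist = HistogramRecord(hist.edges[block.start:block.stop + 1],
                               hist.counts[block], hist.total_sweeps)
    sub_w = WeightTable(weights.edges[block.start:block.stop + 1],
                        weights.lnw[block])
    dos = dos_from_weights(sub_w, sub_hist)
    profile = micro_beta_gamma(dos, smoothing_sigma=smoothing)
    if trim > 0 and profile.gamma.size > 2 * trim + 3:
        profile = MicroProfile(profile.e_beta[trim:-trim],
                               profile.beta[trim:-trim],
                               profile.e_gamma[trim:-trim],
                               profile.gamma[trim:-trim],
                               profile.smoothing_sigma)
    search = profile
    if e_window is not None:
        keep_b = (profile.e_beta >= e_window[0]) & \
                 (profile.e_beta <= e_window[1])
        keep_g = (profile.e_gamma >= e_window[0]) & \
                 (profile.e_gamma <= e_window[1])
        if keep_g.sum() >= 5:
            search = MicroProfile(profile.e_beta[keep_b],
                                  profile.beta[keep_b],
                                  profile.e_gamma[keep_g],
                                  profile.gamma[keep_g],
                                  profile.smoothing_sigma)
    call = classify_transition(search, reference=profile)
    if call.order != "none":
        gamma_ext, e_ext = call.gamma_peak, call.e_trans
    else:
        i = int(np.argmax(np.abs(search.gamma)))
        gamma_ext, e_ext = float(search.gamma[i]), float(search.e_gamma[i])
    return MicroAnalysis(dos, profile, call,
                         gamma_extremum=gamma_ext, e_extremum=e_ext)


def micro_analysis_blocked(weights: WeightTable, ep_series: np.ndarray, *,
                           gsum: np.ndarray | None = None,
                           replicas: int = 12, block_sweeps: int = 5000,
                           smoothing: float = 4.0, min_count: int = 20,
                           trim: int | None = None,
                           e_window: tuple[float, float] | None = None,
                           seed: int = 0) -> MicroAnalysis:
    """Microcanonical profile with pointwise gamma errors from a
    moving-block bootstrap of the production energy series.

    With ``gsum`` (the accumulated pair statistics of the weight
    recursion), ln Omega is estimated as ``-ln W`` after folding the
    production histogram into the accumulated ratio recursion.  Ratios of
    adjacent bins are *local* estimators, so this pools every iteration's
    visits and remains well-behaved when global equilibration across a
    first-order bottleneck is slow (few barrier crossings); the plain
    ``ln H - ln W`` estimator is used when ``gsum`` is absent.

    Each bootstrap replica rebuilds the histogram from randomly drawn
    contiguous blocks (length ``block_sweeps``, preserving autocorrelation)
    of the series and recomputes gamma(Ep); the scatter across replicas
    gives a per-energy standard error.  The transition call then requires
    pointwise significance
    (:func:`semiflex.microcanonical.classify_transition_pointwise`), which
    remains valid when the profile covers only the transition region and
    has no featureless tail to calibrate a global noise floor.
    """
    from .microcanonical import classify_transition_pointwise
    from .sampling import _update_weights
    rng = np.random.default_rng(seed)
    n = ep_series.size
    L = min(block_sweeps, max(1, n // 10))
    n_blocks = max(1, int(np.ceil(n / L)))
    counts, _ = np.histogram(ep_series, bins=weights.edges)
    rep_counts = []
    for _ in range(replicas):
        starts = rng.integers(0, n - L + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(L)[None, :]).ravel()[:n]
        rep_counts.append(np.histogram(ep_series[idx],
                                       bins=weights.edges)[0])
    ok = counts >= min_count
    for rc in rep_counts:
        ok &= rc > 0
    block = _contiguous_block(ok)
    if block.stop - block.start < 8:
        raise ValueError("production series does not cover a contiguous "
                         "energy block; increase sweeps")
    if trim is None:
        trim = max(4, int(0.08 * (block.stop - block.start)))

    def ln_omega_of(counts_vec):
        if gsum is None:
            out = np.full(weights.nbins, -np.inf)
            cov = counts_vec > 0
            out[cov] = np.log(counts_vec[cov].astype(float)) - \
                weights.lnw[cov]
            return out
        tab = WeightTable(weights.edges.copy(), weights.lnw.copy())
        lnw_new = _update_weights(tab, counts_vec, gsum=gsum.copy())
        return -lnw_new

    def dos_of(counts_vec):
        ln_om = ln_omega_of(counts_vec)[block]
        return DensityOfStates(weights.centers[block],
                               ln_om - ln_om.max(), weights.de)

    dos = dos_of(counts)
    profile = micro_beta_gamma(dos, smoothing_sigma=smoothing)
    gammas = [micro_beta_gamma(dos_of(rc), smoothing_sigma=smoothing).gamma
              for rc in rep_counts]
    gamma_err = np.std(np.array(gammas), axis=0, ddof=1)
    if trim > 0 and profile.gamma.size > 2 * trim + 3:
        sl = slice(trim, -trim)
        profile = MicroProfile(profile.e_beta[sl], profile.beta[sl],
                               profile.e_gamma[sl], profile.gamma[sl],
                               profile.smoothing_sigma)
        gamma_err = gamma_err[sl]
    search, search_err = profile, gamma_err
    if e_window is not None:
        keep_b = (profile.e_beta >= e_window[0]) & \
                 (profile.e_beta <= e_window[1])
        keep_g = (profile.e_gamma >= e_window[0]) & \
                 (profile.e_gamma <= e_window[1])
        if keep_g.sum() >= 5:
            search = MicroProfile(profile.e_beta[keep_b],
                                  profile.beta[keep_b],
                                  profile.e_gamma[keep_g],
                                  profile.gamma[keep_g],
                                  profile.smoothing_sigma)
            search_err = gamma_err[keep_g]
    call = classify_transition_pointwise(search, search_err)
    if call.order != "none":
        gamma_ext, e_ext = call.gamma_peak, call.e_trans
    else:
        i = int(np.argmax(np.abs(search.gamma)))
        gamma_ext, e_ext = float(search.gamma[i]), float(search.e_gamma[i])
    return MicroAnalysis(dos, profile, call,
                         gamma_extremum=gamma_ext, e_extremum=e_ext)


@dataclass
class KappaAnalysis:
    kappa: float
    weights: WeightTable
    hist: HistogramRecord
    series: TaggedSeries
    micro: MicroAnalysis
    converged: bool


def analyze_kappa(spec: ModelSpec, N: int, *, M: int = 1,
                  box: float | None = None, seed: int = 0,
                  de: float = 0.5, t_min: float = 0.55, t_hot: float = 2.5,
                  e_floor: float | None = None,
                  sweeps_init: int = 8000, sweeps_max: int = 40_000,
                  max_iter: int = 25, production_sweeps: int = 250_000,
                  production_walkers: int = 1, ladder_init: bool = True,
                  smoothing: float = 4.0) -> KappaAnalysis:
    """Full multicanonical + microcanonical pipeline at one stiffness.

    Pipeline: hot canonical pilot (upper energy bound) -> weight iteration
    covering temperatures [t_min, t_hot] -> reheat -> flat-histogram
    production -> microcanonical profile.  The gamma-extremum search is
    localized around the canonical transition (the specific-heat peak
    temperature mapped to its mean energy), which keeps spurious extrema
    of the poorly sampled tails out of the classification.
    """
    seeds = _sub_seeds(seed, 8)
    conf = initial_conformation(spec, N, M, box, seed=seeds[0])
    e_max = pilot_energy_range(conf, spec, t_hot, seed=seeds[1])
    if e_floor is None:
        e_floor = -6.0 * spec.eps * N * M
    muca = iterate_muca_weights(
        conf, spec, e_floor, e_max, de=de, seed=seeds[2],
        sweeps_init=sweeps_init, sweeps_max=sweeps_max, max_iter=max_iter,
        beta_max=1.0 / t_min, t_hot=t_hot, ladder_init=ladder_init)
    # production uses several independently seeded walkers, all continuing
    # from the iteration's end state (which the downward weight march
    # typically leaves on the low-energy branch; unfolding upward crosses
    # the transition bottleneck far more readily than folding from a hot
    # start).  Summed walker histograms average over the rare barrier
    # crossings that a single walker may miss entirely.
    wseeds = _sub_seeds(seeds[3], production_walkers)
    parts = []
    run = None
    for w, ws in enumerate(wseeds):
        cw = muca.conf if w == 0 else muca.conf.copy()
        s_w, r_w = muca_production(cw, spec, muca.weights,
                                   production_sweeps // production_walkers,
                                   seed=ws)
        parts.append(s_w)
        if run is None:
            run = r_w
        else:
            run.hist.counts = run.hist.counts + r_w.hist.counts
    series = TaggedSeries(
        np.concatenate([p.ep for p in parts]),
        np.concatenate([p.lnw for p in parts]),
        {k: np.concatenate([p.obs[k] for p in parts])
         for k in parts[0].obs})
    # localize the transition canonically: CV peak -> <Ep>(T_c)
    t_grid = np.linspace(1.05 * t_min, 0.95 * t_hot, 40)
    cv = canonical_curve(series, t_grid)["dOdT"].to_numpy()
    t_c = float(t_grid[int(np.argmax(cv))])
    ep_c = reweight_mean_energy(series, t_c)
    cov = np.nonzero(run.hist.counts)[0]
    span = (run.hist.centers[cov[-1]] - run.hist.centers[cov[0]]
            if cov.size else 0.0)
    half = max(15.0 * spec.eps, 0.2 * span)
    micro = micro_analysis_blocked(muca.weights, series.ep,
                                   smoothing=smoothing,
                                   e_window=(ep_c - half, ep_c + half),
                                   seed=seeds[6] ^ 0x7F)
    return KappaAnalysis(spec.kappa, muca.weights, run.hist, series, micro,
                         muca.converged)


def reweight_mean_energy(series: TaggedSeries, T: float) -> float:
    from .reweighting import reweight
    return float(reweight(series, 1.0 / T, series.ep).value)


def scan_phase_diagram(spec: ModelSpec, N: int, kappas, t_grid, *,
                       M: int = 1, box: float | None = None, seed: int = 0,
                       **kw):
    """Transition-line scan over a stiffness grid.

    For each kappa: multicanonical run, reweighted CV(T), dRgyr^2/dT (and
    dGamma2/dT for multi-chain systems) on the temperature grid, peak
    positions of each curve, plus the background observable grid
    (<Rgyr^2> single chain, <CR> multi-chain).  Returns
    ``(peaks, background, analyses)``: a tidy DataFrame of
    (kappa, T_peak, observable, height, converged), the background grid,
    and the per-kappa analysis objects.  Unconverged weights flag the rows
    but do not stop the scan.
    """
    t_grid = np.asarray(t_grid, float)
    rows = []
    bg_rows = []
    analyses = {}
    seeds = _sub_seeds(seed, len(list(kappas)))
    for s, kappa in zip(seeds, kappas):
        ana = analyze_kappa(spec.with_kappa(float(kappa)), N, M=M, box=box,
                            seed=s, **kw)
        analyses[float(kappa)] = ana
        curves = {"cv": canonical_curve(ana.series, t_grid),
                  "drg2_dT": canonical_curve(ana.series, t_grid, "rg2")}
        if M > 1:
            curves["dgamma2_dT"] = canonical_curve(ana.series, t_grid,
                                                   "gamma2")
        for name, df in curves.items():
            y = df["dOdT"].to_numpy()
            for t_peak in scan_peaks(t_grid, y):
                h = float(np.interp(t_peak, t_grid, y))
                rows.append({"kappa": kappa, "T_peak": t_peak,
                             "observable": name, "height": h,
                             "converged": ana.converged})
        bg_name = "cr" if M > 1 else "rg2"
        bg = canonical_curve(ana.series, t_grid, bg_name, derivative=False)
        for T, v in zip(bg["T"], bg["mean"]):
            bg_rows.append({"kappa": kappa, "T": T, bg_name: v})
    return pd.DataFrame(rows), pd.DataFrame(bg_rows), analyses


def gamma_peak_sign(spec: ModelSpec, N: int, kappa: float, *, seed: int = 0,
                    **kw) -> float:
    """Signed transition gamma peak at one stiffness (scan helper).

    Positive iff the transition classifies first-order (back-bending
    present); an unclassifiable (sub-noise) profile counts as "no
    back-bend", i.e. weakly negative.
    """
    ana = analyze_kappa(spec.with_kappa(kappa), N, seed=seed, **kw)
    call = ana.micro.call
    if call.order == "first-order":
        return abs(call.gamma_peak)
    if call.order == "second-order":
        return -abs(call.gamma_peak)
    return -call.threshold


def find_gamma_crossover(spec: ModelSpec, N: int, *, k_lo: float = 2.0,
                         k_hi: float = 10.0, tol: float = 1.0,
                         seed: int = 0, **kw):
    """Bracket the stiffness where the gamma-peak sign flips.

    ``k_lo`` must show a negative peak (second-order-like collapse) and
    ``k_hi`` a positive one (first-order-like folding); bisection narrows
    the bracket to width ``tol`` and the midpoint estimates the crossover.
    Returns ``(kappa_cross, history)``.
    """
    history = []
    seeds = iter(_sub_seeds(seed, 32))
    g_lo = gamma_peak_sign(spec, N, k_lo, seed=next(seeds), **kw)
    g_hi = gamma_peak_sign(spec, N, k_hi, seed=next(seeds), **kw)
    history += [(k_lo, g_lo), (k_hi, g_hi)]
    if not (g_lo < 0 < g_hi):
        raise RuntimeError(
            f"bracket endpoints do not straddle the crossover: "
            f"gamma({k_lo})={g_lo:.3g}, gamma({k_hi})={g_hi:.3g}")
    while k_hi - k_lo > tol:
        k_mid = 0.5 * (k_lo + k_hi)
        g_mid = gamma_peak_sign(spec, N, k_mid, seed=next(seeds), **kw)
        history.append((k_mid, g_mid))
        if g_mid < 0:
            k_lo = k_mid
        else:
            k_hi = k_mid
    return 0.5 * (k_lo + k_hi), history
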