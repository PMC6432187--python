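"""Canonical and generalized-ensemble sampling.

Provides canonical production runs, the multicanonical (flat-histogram)
weight iteration with optional independent parallel walkers, the
microcanonical-ensemble weight of a fixed total energy, and a simple
parallel-tempering driver.

Multicanonical idea: the canonical partition function factorizes into the
conformational density of states and the Boltzmann factor,
``Z = \\int dEp  Omega(Ep) e^{-beta Ep}``.  Replacing the Boltzmann factor
by a generalized weight ``W(Ep) ~ 1/Omega(Ep)`` makes the sampled energy
histogram flat, so one simulation covers the whole temperature window of
interest; canonical averages are recovered afterwards by reweighting
(:mod:`semiflex.reweighting`).  ``W`` is built iteratively: sample under
the current weights, then divide out the visited histogram.  The update is
formulated on nearest-neighbour log-weight ratios with statistics-weighted
damping, so every iteration's counts accumulate and unvisited bins are
carried forward untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import kernels
from .models import Conformation, EnergyBreakdown, ModelSpec, total_energy
from .moves import MOVE_KINDS, MoveSpec, default_move_mix

__all__ = [
    "WeightTable", "HistogramRecord", "RunResult", "MucaResult",
    "run_canonical", "run_generalized", "iterate_muca_weights",
    "parallel_muca", "muca_production", "microcanonical_weight",
    "nve_weight_table", "parallel_tempering", "tune_amplitudes",
]


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# weight tables and histograms
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Binned generalized weight ln W(Ep) on a uniform energy grid."""

    edges: np.ndarray   # (nbins + 1,) uniform bin edges over Ep
    lnw: np.ndarray     # (nbins,) log-weight per bin

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.lnw = np.asarray(self.lnw, float)
        if self.edges.size != self.lnw.size + 1:
            raise ValueError("edges must have one more entry than lnw")
        widths = np.diff(self.edges)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-10):
            raise ValueError("weight table requires a uniform energy grid")

    @property
    def e0(self) -> float:
        return float(self.edges[0])

    @property
    def de(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def nbins(self) -> int:
        return self.lnw.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_index(self, ep):
        return np.floor((np.asarray(ep, float) - self.e0) / self.de).astype(int)

    def lookup(self, ep):
        """ln W at the bin containing ep; -inf outside the covered range."""
        idx = self.bin_index(ep)
        scalar = idx.ndim == 0
        idx = np.atleast_1d(idx)
        out = np.full(idx.shape, -np.inf)
        ok = (idx >= 0) & (idx < self.nbins)
        out[ok] = self.lnw[idx[ok]]
        return float(out[0]) if scalar else out

    @classmethod
    def uniform(cls, e_min: float, e_max: float, de: float) -> "WeightTable":
        nbins = max(1, int(np.ceil((e_max - e_min) / de)))
        edges = e_min + de * np.arange(nbins + 1)
        return cls(edges, np.zeros(nbins))

    @classmethod
    def from_function(cls, fn, e_min: float, e_max: float,
                      de: float) -> "WeightTable":
        tab = cls.uniform(e_min, e_max, de)
        tab.lnw = np.asarray(fn(tab.centers), float)
        return tab

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# bin_left\tbin_right\tlnW\n")
            for lo, hi, w in zip(self.edges[:-1], self.edges[1:], self.lnw):
                fh.write(f"{float(lo)!r}\t{float(hi)!r}\t{float(w)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "WeightTable":
        data = np.loadtxt(path, comments="#", ndmin=2)
        edges = np.append(data[:, 0], data[-1, 1])
        return cls(edges, data[:, 2])


@dataclass
class HistogramRecord:
    """Visit counts on the same grid as a WeightTable."""

    edges: np.ndarray
    counts: np.ndarray
    total_sweeps: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.counts = np.asarray(self.counts, np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative histogram count")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def flatness(self, window=None) -> float:
        """min/mean visit ratio over the (sliced) covered range."""
        c = self.counts if window is None else self.counts[window]
        if c.size == 0 or c.sum() == 0:
            return 0.0
        return float(c.min() / c.mean())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_sweeps={self.total_sweeps}\n")
            fh.write("# bin_left\tbin_right\tcount\n")
            for lo, hi, n in zip(self.edges[:-1], self.edges[1:],
                                 self.counts):
                fh.write(f"{float(lo)!r}\t{float(hi)!r}\t{int(n)}\n")

    @classmethod
    def from_tsv(cls, path) -> "HistogramRecord":
        total = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# total_sweeps="):
                total = int(first.split("=", 1)[1])
        data = np.loadtxt(path, comments="#", ndmin=2)
        edges = np.append(data[:, 0], data[-1, 1])
        return cls(edges, data[:, 2].astype(np.int64), total)


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Time series and bookkeeping of one MC run (one walker)."""

    series: np.ndarray                 # (n_measured, 8), kernels.SERIES_COLUMNS
    hist: HistogramRecord
    acceptance: dict
    conf: Conformation
    energy: EnergyBreakdown
    seed: int
    sweeps: int
    discard: int

    columns = kernels.SERIES_COLUMNS

    def col(self, name: str) -> np.ndarray:
        return self.series[:, self.columns.index(name)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.series, columns=list(self.columns))


def _mix_to_kernel(mix: list[MoveSpec], spec: ModelSpec):
    kinds = list(MOVE_KINDS)
    w = np.zeros(4)
    amps = np.zeros(4)
    for m in mix:
        i = kinds.index(m.move_kind)
        w[i] += m.weight
        amps[i] = m.amplitude
    if spec.model_kind == "bead-stick" and w[0] > 0:
        raise ValueError("bead-stick forbids local displacements")
    if w.sum() <= 0:
        raise ValueError("move mix has zero total weight")
    pcum = np.cumsum(w / w.sum())
    return pcum, amps


_NO_TABLE = WeightTable(np.array([-1e300, 1e300]), np.zeros(1))


def _run(conf: Conformation, spec: ModelSpec, *, use_table: int,
         beta: float, table: WeightTable | None, n_sweeps: int,
         discard: int, seed: int, mix=None,
         resync_every: int = 20_000) -> RunResult:
    if mix is None:
        mix = default_move_mix(spec, conf.n_chains, conf.box)
    pcum, amps = _mix_to_kernel(mix, spec)
    tab = table if table is not None else _NO_TABLE
    n_sweeps = int(n_sweeps)
    discard = min(int(discard), max(0, n_sweeps - 1))
    e_start = total_energy(conf, spec)
    if not e_start.finite:
        raise ValueError("starting conformation has non-finite energy")
    if use_table:
        i0 = tab.bin_index(e_start.ep)
        if not (0 <= i0 < tab.nbins):
            raise ValueError(
                f"starting energy {e_start.ep:.4g} outside weight-table range")
    seed = int(seed) & 0x7FFFFFFF
    series, hist, acc, att, elj, ebend, efene = kernels.run_mc(
        conf.positions, conf.n_per_chain, conf.n_chains,
        *spec.kernel_params(conf.box_or_zero),
        use_table, float(beta), tab.e0, tab.de, tab.lnw,
        int(n_sweeps), int(discard), seed,
        pcum, amps[0], amps[1], amps[2], amps[3], int(resync_every))
    acceptance = {k: (int(acc[i]), int(att[i]))
                  for i, k in enumerate(MOVE_KINDS)}
    return RunResult(
        series=series,
        hist=HistogramRecord(tab.edges.copy(), hist, n_sweeps - discard),
        acceptance=acceptance, conf=conf,
        energy=EnergyBreakdown(elj, ebend, efene, spec.kappa),
        seed=seed, sweeps=n_sweeps, discard=discard)


def run_canonical(conf: Conformation, spec: ModelSpec, T: float,
                  n_sweeps: int, *, discard: int = 0, seed: int = 0,
                  mix=None, resync_every: int = 20_000) -> RunResult:
    """Metropolis run at temperature T (kB = 1).  Modifies conf in place."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return _run(conf, spec, use_table=0, beta=1.0 / T, table=None,
                n_sweeps=n_sweeps, discard=discard, seed=seed, mix=mix,
                resync_every=resync_every)


def run_generalized(conf: Conformation, spec: ModelSpec, table: WeightTable,
                    n_sweeps: int, *, discard: int = 0, seed: int = 0,
                    mix=None, resync_every: int = 20_000) -> RunResult:
    """Run under a fixed generalized weight table (muca / NVE / custom)."""
    return _run(conf, spec, use_table=1, beta=0.0, table=table,
                n_sweeps=n_sweeps, discard=discard, seed=seed, mix=mix,
                resync_every=resync_every)


def tune_amplitudes(conf: Conformation, spec: ModelSpec, *, beta: float,
                    mix=None, seed: int = 0, target=(0.3, 0.6),
                    batches: int = 8, batch_sweeps: int = 200):
    """Adjust move amplitudes toward 30-60% acceptance.

    Equilibration-phase helper only: amplitudes must be frozen before
    measurement to preserve detailed balance.  Returns the tuned mix.
    """
    if mix is None:
        mix = default_move_mix(spec, conf.n_chains, conf.box)
    mix = list(mix)
    caps = {"local-displacement": 2.0 * spec.bond_length,
            "crankshaft": np.pi, "pivot": np.pi,
            "chain-translation": (conf.box / 2 if conf.box else 1e9)}
    for b, s in enumerate(_sub_seeds(seed, batches)):
        res = run_canonical(conf, spec, 1.0 / beta, batch_sweeps, seed=s,
                            mix=mix, resync_every=0)
        new = []
        for m in mix:
            acc, att = res.acceptance[m.move_kind]
            amp = m.amplitude
            if att > 0:
                rate = acc / att
                if rate > target[1]:
                    amp = min(amp * 1.5, caps[m.move_kind])
                elif rate < target[0]:
                    amp *= 0.6
            new.append(MoveSpec(m.move_kind, amp, m.weight))
        mix = new
    return mix


# ---------------------------------------------------------------------------
# multicanonical weight iteration
# ---------------------------------------------------------------------------

@dataclass
class MucaResult:
    weights: WeightTable
    confs: list                       # final walker conformations
    converged: bool
    n_iterations: int
    flatness_history: list = field(default_factory=list)
    coverage: np.ndarray | None = None
    # grid slice targeted by the flatness criterion
    window: slice = field(default_factory=lambda: slice(None))
    # accumulated pair statistics of the ratio recursion (nbins - 1,)
    gsum: np.ndarray | None = None

    @property
    def conf(self) -> Conformation:
        return self.confs[0]


def _equilibrate_into_range(conf, spec, table, t_hot, seed, mix):
    """Short canonical runs at t_hot until Ep lies inside the table range."""
    for i, s in enumerate(_sub_seeds(seed, 12)):
        e = total_energy(conf, spec).ep
        idx = table.bin_index(e)
        if 0 <= idx < table.nbins:
            return
        run_canonical(conf, spec, t_hot, 500 * (i + 1), seed=s, mix=mix)
    e = total_energy(conf, spec).ep
    raise RuntimeError(
        f"could not equilibrate into weight range: Ep={e:.4g} "
        f"outside [{table.e0:.4g}, {table.edges[-1]:.4g}]")


def _update_weights(table: WeightTable, counts: np.ndarray, *,
                    gsum: np.ndarray | None = None,
                    smooth_window: int = 0) -> np.ndarray:
    """Accumulated-statistics multicanonical recursion on log-weight ratios.

    Works on nearest-neighbour differences ``r_k = lnW_{k+1} - lnW_k`` so
    that bins never visited keep their current ratios (carry-forward with
    no stitching constants) and each iteration's correction
    ``ln H_k - ln H_{k+1}`` is damped by the fraction of total statistics
    this iteration contributes to the pair,
    ``kappa_k = g0_k / sum g0_k`` with ``g0_k = H_k H_{k+1}/(H_k+H_{k+1})``.
    With ``gsum=None`` (single-shot mode) the correction is applied in
    full wherever both bins were visited.
    """
    H = counts.astype(float)
    r = np.diff(table.lnw)
    both = (H[:-1] > 0) & (H[1:] > 0)
    g0 = np.zeros(r.size)
    g0[both] = H[:-1][both] * H[1:][both] / (H[:-1][both] + H[1:][both])
    if gsum is None:
        kap = both.astype(float)
    else:
        gsum += g0
        with np.errstate(invalid="ignore", divide="ignore"):
            kap = np.where(gsum > 0, g0 / np.where(gsum > 0, gsum, 1.0), 0.0)
    dr = np.zeros(r.size)
    dr[both] = np.log(H[:-1][both]) - np.log(H[1:][both])
    if smooth_window and smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        dr = np.convolve(dr, k, mode="same")
    r = r + kap * dr
    lnw = np.concatenate([[0.0], np.cumsum(r)])
    return lnw - lnw.max()


def _extrapolate_uncovered(table: WeightTable, cum_cov: np.ndarray,
                           beta_low: float | None = None) -> None:
    """Replace ln W on never-visited edge bins by a linear continuation.

    Bins outside the cumulatively covered range carry no sampling
    information, only the initial guess; a stale too-steep guess there can
    trap the walker at the coverage boundary.  The low-energy side is
    continued with slope ``-beta_low`` when given (the coldest inverse
    temperature of interest): wherever the true beta(Ep) is below that --
    in particular inside a first-order convex intruder -- the walker keeps
    pushing downward, while past the targeted window the true beta exceeds
    it and acts as a soft wall against free-fall into frozen states.
    Without ``beta_low`` (and on the high-energy side) the measured edge
    slope is used, clamped non-positive.
    """
    idx = np.nonzero(cum_cov)[0]
    if idx.size < 2:
        return
    lnw = table.lnw
    centers = table.centers
    ilo, ihi = int(idx[0]), int(idx[-1])
    nfit = min(8, ihi - ilo + 1)
    if ilo > 0:
        if beta_low is not None:
            slope = -beta_low
        else:
            slope = np.polyfit(centers[ilo:ilo + nfit],
                               lnw[ilo:ilo + nfit], 1)[0]
            slope = min(slope, 0.0)
        lnw[:ilo] = lnw[ilo] + slope * (centers[:ilo] - centers[ilo])
    if ihi < lnw.size - 1:
        slope = np.polyfit(centers[ihi - nfit + 1:ihi + 1],
                           lnw[ihi - nfit + 1:ihi + 1], 1)[0]
        slope = min(slope, 0.0)
        lnw[ihi + 1:] = lnw[ihi] + slope * (centers[ihi + 1:] - centers[ihi])


def _flat_window(table: WeightTable, beta_max: float | None,
                 cum_counts: np.ndarray) -> tuple[slice, bool]:
    """Grid slice over which flatness is required, plus a coverage flag.

    The window is the solidly covered part of the grid whose local inverse
    temperature ``-d lnW/dEp`` stays below ``beta_max``; the flag reports
    whether coverage actually reaches that cold edge (within 5%), which is
    required for convergence in ``beta_max`` mode.  "Solid" coverage means
    at least 2% of the typical cumulative visit count: bins right at a
    coverage cliff (e.g. below the ground-state energy) may be hit by a
    rare fluctuation once but can never sample flat.
    """
    nz = cum_counts[cum_counts > 0]
    if nz.size == 0:
        return slice(0, table.nbins), False
    solid = cum_counts >= max(1.0, 0.02 * nz.mean())
    idx = np.nonzero(solid)[0]
    if idx.size == 0:
        return slice(0, table.nbins), False
    ilo, ihi = int(idx[0]), int(idx[-1])
    if beta_max is None:
        return slice(0, table.nbins), True
    lnw_s = gaussian_filter1d(table.lnw, 2.0, mode="nearest")
    beta = -np.gradient(lnw_s, table.centers)
    # the window keeps a 5% margin off the cold edge: bins with local beta
    # right at beta_max are only marginally visited under converged weights
    below = np.nonzero(beta <= 0.95 * beta_max)[0]
    lo_beta = int(below[0]) if below.size else ilo
    cold_ok = lo_beta >= ilo or beta[ilo] >= 0.95 * beta_max
    return slice(max(lo_beta, ilo), ihi + 1), cold_ok


def _ladder_init_weights(conf: Conformation, spec: ModelSpec,
                         table: WeightTable, t_min: float, t_hot: float,
                         seed: int, mix, sweeps: int = 4000,
                         n_temps: int = 8) -> None:
    """Seed ln W by annealing down a temperature ladder.

    Short canonical runs at geometrically spaced temperatures give mean
    energies (E_i, beta_i); interpolating beta(E) and integrating
    ``lnW(E) = -int beta dE`` produces a starting table already close to
    ``1/Omega`` over the covered range, so the flat-histogram recursion only
    needs to polish it.  Low-temperature runs may be stuck out of
    equilibrium; the subsequent iterations correct that bias.
    """
    temps = np.geomspace(t_hot, t_min, n_temps)
    pts = []
    for T, s in zip(temps, _sub_seeds(seed, n_temps)):
        res = run_canonical(conf, spec, T, sweeps, discard=sweeps // 4,
                            seed=s, mix=mix)
        pts.append((float(res.col("ep").mean()), 1.0 / T))
    pts.sort()
    e_pts = np.array([p[0] for p in pts])
    b_pts = np.array([p[1] for p in pts])
    keep = np.concatenate([[True], np.diff(e_pts) > 1e-9])
    centers = table.centers
    beta_of_e = np.interp(centers, e_pts[keep], b_pts[keep])
    lnw = -np.concatenate([[0.0], np.cumsum(
        0.5 * (beta_of_e[1:] + beta_of_e[:-1]) * np.diff(centers))])
    table.lnw = lnw - lnw.max()


def iterate_muca_weights(conf: Conformation, spec: ModelSpec,
                         e_min: float, e_max: float, *,
                         de: float = 0.5, seed: int = 0,
                         sweeps_init: int = 5_000, growth: float = 1.4,
                         sweeps_max: int = 60_000, max_iter: int = 60,
                         flatness: float = 0.5, beta_max: float | None = None,
                         t_hot: float = 3.0, mix=None,
                         smooth_window: int = 0, ladder_init: bool = True,
                         walkers: int = 1) -> MucaResult:
    """Iterate multicanonical weights over [e_min, e_max].

    The table is seeded by a temperature-ladder annealing estimate of
    beta(Ep) (``ladder_init``); each iteration then samples under the
    current weights and applies the accumulated-statistics recursion on
    log-weight ratios (see :func:`_update_weights`), which carries
    unvisited bins forward without stitching artefacts.  Convergence
    requires the production-style flatness criterion min/mean >=
    ``flatness`` over the target window: the full grid by default, or --
    when ``beta_max`` is given -- the covered energy range whose local
    inverse temperature ``-d lnW/dEp`` does not exceed ``beta_max`` (i.e.
    the weights span all temperatures down to ``1/beta_max``).

    With ``walkers > 1``, independent chains sample under the same table and
    their histograms are summed before each update (the parallel
    multicanonical scheme); ``walkers=1`` is the serial algorithm.
    """
    table = WeightTable.uniform(e_min, e_max, de)
    seeds = _sub_seeds(seed, max_iter * walkers + walkers)
    confs = [conf if w == 0 else conf.copy() for w in range(walkers)]
    if ladder_init:
        t_cold = 1.0 / beta_max if beta_max else t_hot / 4.0
        _ladder_init_weights(confs[0], spec, table, t_cold, t_hot,
                             seeds[0] ^ 0x5A5A, mix)
        # the anneal leaves the walker in a (possibly trapped) cold state;
        # restart exploration from the hot end under the estimated weights
        run_canonical(confs[0], spec, t_hot, 3000, seed=seeds[0] ^ 0x3C3C,
                      mix=mix)
    for w, cw in enumerate(confs):
        _equilibrate_into_range(cw, spec, table, t_hot, seeds[w], mix)
    cum_counts = np.zeros(table.nbins, np.int64)
    gsum = np.zeros(table.nbins - 1)
    hist_flat = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sweeps = int(min(sweeps_init * growth ** (it - 1), sweeps_max))
        counts = np.zeros(table.nbins, np.int64)
        for w, cw in enumerate(confs):
            res = run_generalized(cw, spec, table, sweeps,
                                  discard=max(1, sweeps // 10),
                                  seed=seeds[walkers + (it - 1) * walkers + w],
                                  mix=mix)
            counts += res.hist.counts
        cum_counts += counts
        win, cold_ok = _flat_window(table, beta_max, cum_counts)
        sub = counts[win]
        ratio = float(sub.min() / sub.mean()) if sub.size and sub.sum() else 0.0
        hist_flat.append(ratio)
        if ratio >= flatness and cold_ok:
            converged = True
            break
        table.lnw = _update_weights(table, counts, gsum=gsum,
                                    smooth_window=smooth_window)
        _extrapolate_uncovered(table, cum_counts > 0, beta_low=beta_max)
    return MucaResult(weights=table, confs=confs, converged=converged,
                      n_iterations=it, flatness_history=hist_flat,
                      coverage=cum_counts > 0,
                      window=_flat_window(table, beta_max, cum_counts)[0],
                      gsum=gsum)


def parallel_muca(conf: Conformation, spec: ModelSpec, e_min: float,
                  e_max: float, walkers: int, **kw) -> MucaResult:
    """Parallel multicanonical weight iteration (independent walkers whose
    per-iteration histograms are summed before each weight update)."""
    return iterate_muca_weights(conf, spec, e_min, e_max,
                                walkers=walkers, **kw)


def muca_production(conf: Conformation, spec: ModelSpec, table: WeightTable,
                    n_sweeps: int, *, discard: int | None = None,
                    seed: int = 0, mix=None):
    """Production run under converged (fixed) weights.

    Returns ``(series, run)`` where ``series`` is a
    :class:`semiflex.reweighting.TaggedSeries` ready for canonical
    reweighting and ``run`` the raw :class:`RunResult`.
    """
    from .reweighting import TaggedSeries
    if discard is None:
        discard = max(1, n_sweeps // 10)
    run = run_generalized(conf, spec, table, n_sweeps, discard=discard,
                          seed=seed, mix=mix)
    return TaggedSeries.from_run(run, table), run


# ---------------------------------------------------------------------------
# microcanonical (fixed total energy) weights
# ---------------------------------------------------------------------------

def microcanonical_weight(ep, e_total: float, ndof: int):
    """Weight of the fixed-total-energy ensemble, (E - Ep)^((Ndof-2)/2).

    The kinetic energy acts as a finite reservoir: configurations with
    ``Ep >= E`` have zero weight (move rejection).  ``ndof`` is the number
    of momentum degrees of freedom (3N for N independent beads).
    """
    ep_arr = np.asarray(ep, float)
    scalar = ep_arr.ndim == 0
    ep_arr = np.atleast_1d(ep_arr)
    out = np.zeros(ep_arr.shape)
    ok = ep_arr < e_total
    out[ok] = (e_total - ep_arr[ok]) ** ((ndof - 2) / 2.0)
    return float(out[0]) if scalar else out


def nve_weight_table(e_total: float, ndof: int, e_min: float, e_max: float,
                     de: float = 0.5) -> WeightTable:
    """WeightTable realizing the microcanonical weight on an energy grid."""
    tab = WeightTable.uniform(e_min, e_max, de)
    with np.errstate(divide="ignore"):
        w = microcanonical_weight(tab.centers, e_total, ndof)
        tab.lnw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    return tab


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------

def parallel_tempering(conf: Conformation, spec: ModelSpec,
                       temperatures, n_sweeps: int, *,
                       swap_interval: int = 100, seed: int = 0,
                       discard: int = 0, mix=None):
    """Replica exchange over a temperature ladder.

    Each replica runs canonically in chunks of ``swap_interval`` sweeps;
    after each chunk, neighbouring replicas attempt a conformation swap
    accepted with ``min(1, exp(dbeta * dEp))``.  ``swap_interval <= 0``
    disables swaps, leaving independent canonical runs.

    Returns ``(results, swap_stats)``: per-temperature post-discard series
    (stacked over chunks) and a dict with attempt/accept counts per
    neighbour pair.
    """
    temps = [float(t) for t in temperatures]
    k = len(temps)
    confs = [conf.copy() for _ in range(k)]
    chunk = swap_interval if swap_interval > 0 else n_sweeps
    n_chunks = int(np.ceil(n_sweeps / chunk))
    seeds = _sub_seeds(seed, n_chunks * k + 1)
    swap_rng = np.random.default_rng(seeds[-1])
    series = [[] for _ in range(k)]
    attempts = dict.fromkeys(range(k - 1), 0)
    accepts = dict.fromkeys(range(k - 1), 0)
    done = 0
    energies = [total_energy(c, spec).ep for c in confs]
    for ch in range(n_chunks):
        sw = min(chunk, n_sweeps - done)
        for r in range(k):
            res = run_canonical(confs[r], spec, temps[r], sw,
                                seed=seeds[ch * k + r], mix=mix)
            energies[r] = res.energy.ep
            lo = max(0, discard - done)
            if lo < sw:
                series[r].append(res.series[lo:])
        done += sw
        if swap_interval > 0 and done < n_sweeps:
            for p in range(ch % 2, k - 1, 2):
                attempts[p] += 1
                dbeta = 1.0 / temps[p] - 1.0 / temps[p + 1]
                dep = energies[p] - energies[p + 1]
                if dbeta * dep >= 0 or swap_rng.random() < np.exp(dbeta * dep):
                    accepts[p] += 1
                    confs[p], confs[p + 1] = confs[p + 1], confs[p]
                    energies[p], energies[p + 1] = energies[p + 1], energies[p]
    out = [np.concatenate(s, axis=0) if s else np.empty((0, 8))
           for s in series]
    return out, {"attempts": attempts, "accepts": accepts,
                 "temperatures": temps}
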