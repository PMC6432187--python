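"""Microcanonical analysis: density of states, entropy derivatives and
finite-size transition classification.

A flat-histogram run gives the conformational density of states directly:
``ln Omega(Ep) = ln H(Ep) - ln W(Ep)`` bin-wise (additive constant
arbitrary).  From the conformational entropy ``S = ln Omega`` (kB = 1) the
microcanonical inverse temperature ``beta(Ep) = dS/dEp`` and its derivative
``gamma(Ep) = dbeta/dEp`` follow by centred finite differences on a
staggered grid (beta at bin boundaries, gamma back at bin centres).

Transition classification for finite systems: a *positive* peak in gamma
corresponds to back-bending of beta(Ep) -- the convex-intruder signature of
a first-order transition, accompanied by a double-peaked canonical energy
distribution.  A *negative* peak (inflection of beta with negative slope)
signals a second-order transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .sampling import HistogramRecord, WeightTable


@dataclass
class DensityOfStates:
    """Binned ln Omega(Ep) over the covered part of a weight table."""

    centers: np.ndarray      # Ep bin centres (covered bins only)
    ln_omega: np.ndarray     # ln Omega, normalized to max 0
    de: float                # bin width
    provenance: str = ""     # e.g. weight-table iteration id

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.ln_omega = np.asarray(self.ln_omega, float)
        if not np.all(np.isfinite(self.ln_omega)):
            raise ValueError("ln Omega must be finite on covered bins")


@dataclass
class MicroProfile:
    """beta(Ep) on bin boundaries, gamma(Ep) on bin centres, extrema."""

    e_beta: np.ndarray       # boundary energies where beta is defined
    beta: np.ndarray
    e_gamma: np.ndarray      # centre energies where gamma is defined
    gamma: np.ndarray
    smoothing_sigma: float   # Gaussian smoothing applied to ln Omega (bins)


def dos_from_weights(weights: WeightTable, hist: HistogramRecord,
                     provenance: str = "") -> DensityOfStates:
    """ln Omega = ln H_production - ln W on visited bins (max fixed to 0)."""
    if hist.counts.size != weights.nbins:
        raise ValueError("histogram grid does not match weight table")
    cov = hist.counts > 0
    if not cov.any():
        raise ValueError("empty production histogram")
    ln_om = np.log(hist.counts[cov].astype(float)) - weights.lnw[cov]
    ln_om -= ln_om.max()
    return DensityOfStates(weights.centers[cov], ln_om, weights.de,
                           provenance)


def micro_beta_gamma(dos: DensityOfStates,
                     smoothing_sigma: float = 2.0) -> MicroProfile:
    """Centred finite differences of (optionally smoothed) ln Omega.

    beta lives on the staggered boundary grid (first difference), gamma
    back on the centre grid (second difference), so both are centred.
    ``smoothing_sigma`` is the Gaussian kernel width in bins (0 disables);
    the ~4 sigma of points contaminated by the smoothing boundary padding
    are dropped at each end.
    """
    s = dos.ln_omega
    if smoothing_sigma > 0:
        s = gaussian_filter1d(s, smoothing_sigma, mode="nearest")
    e = dos.centers
    beta = np.diff(s) / np.diff(e)
    e_beta = 0.5 * (e[:-1] + e[1:])
    gamma = np.diff(beta) / np.diff(e_beta)
    e_gamma = e[1:-1]
    k = int(np.ceil(4 * smoothing_sigma))
    if k > 0 and gamma.size > 2 * k + 3:
        beta, e_beta = beta[k:-k], e_beta[k:-k]
        gamma, e_gamma = gamma[k:-k], e_gamma[k:-k]
    return MicroProfile(e_beta, beta, e_gamma, gamma,
                        smoothing_sigma=smoothing_sigma)


@dataclass(frozen=True)
class TransitionCall:
    order: str               # "first-order" | "second-order" | "none"
    e_trans: float | None    # gamma-extremum location Ep'
    gamma_peak: float | None
    threshold: float


def classify_transition(profile: MicroProfile, *,
                        noise_factor: float = 3.0,
                        tail_fraction: float = 0.25,
                        reference: MicroProfile | None = None
                        ) -> TransitionCall:
    """Classify the dominant transition from the gamma(Ep) profile.

    Back-bending of beta(Ep) -- any *positive* gamma peak above the noise
    threshold -- classifies the transition as first order (its location is
    the transition energy Ep').  A positive peak of a back-bend is always
    flanked by deeper negative wells, so positivity is checked first;
    without it, a negative gamma peak (inflection of beta with negative
    slope) classifies as second order.  The threshold is ``noise_factor``
    times the median |gamma| over the high-energy tail, where gamma of a
    featureless system hovers around zero; when the profile has been
    restricted to a transition window, ``reference`` supplies the full
    profile whose tail defines that noise floor.
    """
    g = profile.gamma
    if g.size < 3:
        return TransitionCall("none", None, None, np.inf)
    g_noise = (reference.gamma if reference is not None else g)
    ntail = max(3, int(tail_fraction * g_noise.size))
    thresh = noise_factor * float(np.median(np.abs(g_noise[-ntail:])))
    if thresh == 0.0:
        thresh = noise_factor * float(np.abs(g_noise[-ntail:]).mean()
                                      + 1e-300)
    i_max = int(np.argmax(g))
    if g[i_max] > thresh:
        return TransitionCall("first-order", float(profile.e_gamma[i_max]),
                              float(g[i_max]), thresh)
    i_min = int(np.argmin(g))
    if g[i_min] < -thresh:
        return TransitionCall("second-order", float(profile.e_gamma[i_min]),
                              float(g[i_min]), thresh)
    return TransitionCall("none", None, None, thresh)


def classify_transition_pointwise(profile: MicroProfile,
                                  gamma_err: np.ndarray, *,
                                  n_sigma: float = 3.0) -> TransitionCall:
    """Transition-order call using pointwise gamma error bars.

    Preferred when the profile is restricted to the transition region and
    no featureless tail exists to calibrate a global noise floor.  A bin
    with ``gamma - n_sigma * err > 0`` establishes back-bending (first
    order); otherwise a bin with ``gamma + n_sigma * err < 0`` gives a
    significant negative peak (second order).
    """
    g = profile.gamma
    if g.size < 3 or gamma_err.shape != g.shape:
        return TransitionCall("none", None, None, np.inf)
    sig_pos = g - n_sigma * gamma_err
    if np.any(sig_pos > 0):
        i = int(np.argmax(sig_pos))
        return TransitionCall("first-order", float(profile.e_gamma[i]),
                              float(g[i]), float(n_sigma * gamma_err[i]))
    sig_neg = g + n_sigma * gamma_err
    if np.any(sig_neg < 0):
        i = int(np.argmin(sig_neg))
        return TransitionCall("second-order", float(profile.e_gamma[i]),
                              float(g[i]), float(n_sigma * gamma_err[i]))
    return TransitionCall("none", None, None,
                          float(n_sigma * np.median(gamma_err)))


def rescaled_beta(profile: MicroProfile, e_trans: float):
    """Recentre beta(Ep) on the transition point.

    Returns ``(Ep - Ep', beta - beta(Ep'))`` -- a pure transformation used
    to overlay back-bending curves for different stiffnesses; the curve
    passes through the origin and monotonicity is preserved.
    """
    b_at = np.interp(e_trans, profile.e_beta, profile.beta)
    return profile.e_beta - e_trans, profile.beta - b_at


def canonical_energy_moment(dos: DensityOfStates, beta: float,
                            power: int = 1) -> float:
    """<Ep^power> at inverse temperature beta by quadrature over Omega(Ep).

    Independent consistency check for reweighted canonical averages:
    integrates ``Ep^p Omega(Ep) e^{-beta Ep}`` over the estimated density
    of states (log-sum-exp stabilized).
    """
    lng = dos.ln_omega - beta * dos.centers
    lng -= lng.max()
    w = np.exp(lng)
    return float(np.dot(w, dos.centers ** power) / w.sum())
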