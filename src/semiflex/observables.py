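"""Structural and aggregation observables of polymer conformations.

Single-chain shape: squared radius of gyration and end-to-end distance.
Aggregation (M >= 2 chains): the end-to-end correlation parameter ``CR``
(a nematic-like order parameter distinguishing aligned bundles, CR = 1,
from uncorrelated chains, CR = 1/3) and the phase-separation parameter
``Gamma2`` (mean squared minimal-image distance between chain centres of
mass, which drops sharply upon aggregation).

Centres of mass are computed from unwrapped chain coordinates -- valid in
the dilute regime where the chain extent is below half the box edge -- and
only inter-chain differences are minimal-imaged.
"""

from __future__ import annotations

import numpy as np

from .models import Conformation, minimal_image

#: end-to-end vectors shorter than this are treated as undefined directions
REE_EPS = 1e-12


def radius_of_gyration_sq(chain: np.ndarray) -> float:
    """Rgyr^2 = sum_i (r_i - r_cm)^2 / N on unwrapped chain coordinates."""
    r = np.asarray(chain, float)
    d = r - r.mean(axis=0)
    return float(np.einsum("ij,ij->", d, d) / len(r))


def end_to_end(chain: np.ndarray):
    """End-to-end distance |r_1 - r_N| and its unit vector.

    For closed or degenerate chains (Ree below ``REE_EPS``) the direction
    is undefined and None is returned in its place; such chains are
    excluded from CR.
    """
    r = np.asarray(chain, float)
    v = r[0] - r[-1]
    n = float(np.linalg.norm(v))
    if n < REE_EPS:
        return n, None
    return n, v / n


def end_to_end_correlation(unit_vectors) -> float:
    """CR = (2 / M(M-1)) sum_{i<j} (u_i . u_j)^2.

    Mean squared pairwise dot product of the per-chain end-to-end unit
    vectors; per-chain head/tail sign drops out through the square.
    Entries that are None (undefined direction) are excluded pairwise and
    the denominator adjusted; with fewer than one valid pair the result is
    NaN.
    """
    vecs = [None if u is None else np.asarray(u, float) for u in unit_vectors]
    if len(vecs) < 2:
        raise ValueError("CR requires at least two chains")
    for u in vecs:
        if u is not None and abs(np.linalg.norm(u) - 1.0) > 1e-8:
            raise ValueError("end-to-end vectors must be unit length")
    s = 0.0
    npair = 0
    for i in range(len(vecs)):
        if vecs[i] is None:
            continue
        for j in range(i + 1, len(vecs)):
            if vecs[j] is None:
                continue
            s += float(np.dot(vecs[i], vecs[j])) ** 2
            npair += 1
    return s / npair if npair else float("nan")


def phase_separation(coms: np.ndarray, L: float | None = None) -> float:
    """Gamma2 = (1 / 2M^2) sum_{i,j} |r_cm^i - r_cm^j|^2 (ordered pairs).

    Minimal-image differences when a box edge L is given.  Zero when all
    centres of mass coincide; invariant under global translation mod L.
    """
    c = np.asarray(coms, float)
    M = len(c)
    s = 0.0
    for i in range(M):
        for j in range(i + 1, M):
            d = c[i] - c[j]
            if L is not None:
                d = minimal_image(d, L)
            s += float(np.dot(d, d))
    return 2.0 * s / (2.0 * M * M)


def measure(conf: Conformation) -> dict:
    """All per-conformation observables as a dict."""
    chains = [conf.chain(c) for c in range(conf.n_chains)]
    rg2 = [radius_of_gyration_sq(ch) for ch in chains]
    ree = [end_to_end(ch) for ch in chains]
    out = {
        "rg2": float(np.mean(rg2)),
        "ree": float(np.mean([r for r, _ in ree])),
    }
    if conf.n_chains >= 2:
        out["cr"] = end_to_end_correlation([u for _, u in ree])
        coms = np.array([ch.mean(axis=0) for ch in chains])
        out["gamma2"] = phase_separation(coms, conf.box)
    return out


def energy_histogram_2d(elj, ebend, *, weights=None, bins=60, kappa=None):
    """Weighted 2D histogram p(E_LJ, E_bend) and its diagonal projection.

    ``weights`` are per-sample reweighting factors (e.g. canonical weights
    at a target temperature); ``kappa`` enables the projection onto the
    total energy ``E = E_LJ + kappa * E_bend``, the diagonal along which a
    two-peaked 2D distribution may collapse onto a single peak.

    Returns ``(H, xedges, yedges, projection)`` where ``projection`` is
    ``None`` unless ``kappa`` is given, else ``(p_E, E_edges)``.  Total
    weight is conserved by both the 2D histogram and the projection.
    """
    elj = np.asarray(elj, float)
    ebend = np.asarray(ebend, float)
    H, xe, ye = np.histogram2d(elj, ebend, bins=bins, weights=weights)
    proj = None
    if kappa is not None:
        e = elj + kappa * ebend
        proj = np.histogram(e, bins=bins, weights=weights)
    return H, xe, ye, proj
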