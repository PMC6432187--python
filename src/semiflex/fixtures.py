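"""Deterministic conformation and series generators.

These realize the conformation classes that occur across the structural
phase diagrams (rods, hairpins, coils, bundles), parametric torus-knot
curves for the topology machinery, and a two-level toy system with known
closed-form thermodynamics.  Everything is deterministic given its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .models import BEAD_SPRING, BEAD_STICK, Conformation, ModelSpec
from .knots import ClosedCurve


def rod(N: int, spacing: float = 1.0, axis=(1.0, 0.0, 0.0),
        origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Straight rod of N beads: Ree = (N-1) s, Rgyr^2 = s^2 (N^2 - 1) / 12."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    return np.asarray(origin, float) + spacing * np.arange(N)[:, None] * u


def hairpin(N: int, spacing: float = 1.0, gap: float = 1.1) -> np.ndarray:
    """Two antiparallel strands joined by a turn (bead-stick compatible
    when ``gap`` <= 2 spacing: the turn bead keeps all bonds at ``spacing``)."""
    n_arm = (N - 1) // 2
    pts = [np.array([0.0, i * spacing, 0.0]) for i in range(n_arm)]
    # turn: apex offset keeping both adjacent bonds at `spacing`
    h = math.sqrt(max(spacing ** 2 - (gap / 2) ** 2, 0.0))
    top = pts[-1][1]
    pts.append(np.array([gap / 2, top + h, 0.0]))
    for i in range(N - n_arm - 1):
        pts.append(np.array([gap, top - i * spacing, 0.0]))
    return np.array(pts)


def coil(N: int, bond: float = 1.0, seed: int = 0,
         min_sep: float = 0.9) -> np.ndarray:
    """Self-avoiding-ish random walk with fixed bond length (rejection on
    close contacts); deterministic given the seed."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < N:
        for _attempt in range(1000):
            v = rng.normal(size=3)
            v *= bond / np.linalg.norm(v)
            cand = pts[-1] + v
            prev = np.array(pts[:-1]) if len(pts) > 1 else None
            if prev is None or np.min(
                    np.linalg.norm(prev - cand, axis=1)) > min_sep * bond:
                pts.append(cand)
                break
        else:  # extremely unlikely; restart the walk deterministically
            pts = [np.zeros(3)]
    return np.array(pts)


def aligned_bundle(M: int, N: int, spacing: float = 1.0,
                   separation: float = 1.2) -> np.ndarray:
    """M parallel rods on a square lattice of pitch ``separation``: CR = 1."""
    side = math.ceil(math.sqrt(M))
    chains = []
    for c in range(M):
        oy, oz = divmod(c, side)
        chains.append(rod(N, spacing,
                          origin=(0.0, oy * separation, oz * separation)))
    return np.vstack(chains)


def random_bundle(M: int, N: int, spacing: float = 1.0, seed: int = 0,
                  spread: float = 5.0) -> np.ndarray:
    """M rods with i.i.d. uniform random orientations: <CR> = 1/3."""
    rng = np.random.default_rng(seed)
    chains = []
    for c in range(M):
        while True:
            u = rng.normal(size=3)
            n = np.linalg.norm(u)
            if n > 1e-12:
                u /= n
                break
        origin = rng.uniform(0, spread, size=3)
        chains.append(origin + spacing * np.arange(N)[:, None] * u)
    return np.vstack(chains)


def torus_knot(p: int, q: int, n_vertices: int = 120, R: float = 2.0,
               r: float = 1.0) -> ClosedCurve:
    """Standard (p, q) torus-knot polygon.

    Winds p times around the torus axis and q times around the tube;
    (2,3) is the trefoil 3_1, (2,5) the cinquefoil 5_1, (3,4) the 8_19.
    """
    if math.gcd(p, q) != 1:
        raise ValueError("(p, q) must be coprime for a knot")
    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    rad = R + r * np.cos(q * phi)
    verts = np.column_stack([rad * np.cos(p * phi),
                             rad * np.sin(p * phi),
                             r * np.sin(q * phi)])
    return ClosedCurve(verts, provenance="raw")


def torus_knot_open(p: int, q: int, n_vertices: int = 120,
                    **kw) -> np.ndarray:
    """Open-chain version (last vertex dropped) for the closure pipeline."""
    return torus_knot(p, q, n_vertices, **kw).vertices


def two_state_toy(n_samples: int = 10_000, seed: int = 0,
                  energies=(0.0, 1.0)):
    """Flat-weight samples of a two-level system with Omega = {1, 1}.

    Under flat weights both levels are visited equally; canonical
    reweighting must give <Ep> = e1 / (1 + exp(beta (e1 - e0))) + e0 ...
    for the default (0, 1): <Ep>_beta = 1 / (1 + e^beta).
    """
    from .reweighting import TaggedSeries
    rng = np.random.default_rng(seed)
    ep = np.asarray(energies, float)[rng.integers(0, 2, n_samples)]
    return TaggedSeries(ep, np.zeros(n_samples), {})


# ---------------------------------------------------------------------------
# simulation starting conformations
# ---------------------------------------------------------------------------

def initial_conformation(spec: ModelSpec, N: int, M: int = 1,
                         box: float | None = None,
                         seed: int = 0) -> Conformation:
    """Valid starting state: per-chain random coils with the model's bond
    length, chains placed apart (on a grid inside the box if present)."""
    bond = spec.bond_length
    rng = np.random.default_rng(seed)
    chains = []
    ext = bond * N
    for c in range(M):
        ch = coil(N, bond=bond, seed=int(rng.integers(2 ** 31)))
        if box is not None:
            side = math.ceil(M ** (1 / 3))
            cell = box / side
            ix = c % side
            iy = (c // side) % side
            iz = c // (side * side)
            target = (np.array([ix, iy, iz]) + 0.5) * cell
        else:
            target = np.array([0.0, 0.0, c * 2.5 * ext])
        chains.append(ch - ch.mean(axis=0) + target)
    conf = Conformation(np.vstack(chains), N, M, box)
    if box is not None:
        conf.rewrap()
    conf.validate(spec)
    return conf


def make_fixture(kind: str, seed: int = 0, **params):
    """Named deterministic fixtures.

    Kinds: ``rod``, ``hairpin``, ``coil``, ``aligned-bundle``,
    ``random-bundle``, ``torus-knot`` (requires p, q), ``two-state-toy``.
    Conformation-like kinds return raw position arrays; ``torus-knot``
    returns a ClosedCurve; ``two-state-toy`` returns a TaggedSeries.
    """
    table = {
        "rod": rod,
        "hairpin": hairpin,
        "coil": lambda **kw: coil(seed=seed, **kw),
        "aligned-bundle": aligned_bundle,
        "random-bundle": lambda **kw: random_bundle(seed=seed, **kw),
        "torus-knot": torus_knot,
        "two-state-toy": lambda **kw: two_state_toy(seed=seed, **kw),
    }
    if kind not in table:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return table[kind](**params)
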