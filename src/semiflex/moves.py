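"""Model-aware Monte Carlo update set.

This module provides the explicit, inspectable proposal/acceptance API:
:func:`propose` builds a trial update (the minimal changed-bead set plus new
coordinates) and :func:`metropolis_accept` decides on it, either canonically
or with a generalized (binned) weight table.  All proposals are symmetric --
displacements uniform in a cube, rotation angles uniform in ``[-A, A]``,
rotation axes uniform on the sphere -- so the Hastings ratio is always 1.

The production sweep loop in :mod:`semiflex.kernels` implements the same
move set in compiled form; this module is the readable reference used for
geometric invariants and for constructing custom chains of updates.

Move kinds
----------
``local-displacement``
    Single-bead displacement, uniform in a cube.  Forbidden for the
    bead-stick model (it would violate the rigid bonds); there the local
    move is the crankshaft.
``crankshaft``
    Rotation of a single bead about the axis joining its two neighbours
    (end beads rotate about a random axis through their single neighbour).
    Preserves both adjacent bond lengths exactly.
``pivot``
    Rigid rotation of the chain tail beyond a random interior bead about a
    random axis through that bead.
``chain-translation``
    Rigid displacement of a whole chain; only inter-chain energy changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import BEAD_STICK, Conformation, ModelSpec

MOVE_KINDS = ("local-displacement", "crankshaft", "pivot", "chain-translation")


@dataclass(frozen=True)
class MoveSpec:
    """One entry of the move mix: kind, amplitude and selection weight."""

    move_kind: str
    amplitude: float          # length for displacements, radians for rotations
    weight: float             # selection probability mass

    def __post_init__(self) -> None:
        if self.move_kind not in MOVE_KINDS:
            raise ValueError(f"unknown move kind {self.move_kind!r}")
        if self.amplitude < 0 or self.weight < 0:
            raise ValueError("amplitude and weight must be non-negative")


def default_move_mix(spec: ModelSpec, n_chains: int = 1,
                     box: float | None = None) -> list[MoveSpec]:
    """Default move mixture.

    Single chain: local move (crankshaft for bead-stick, displacement +
    crankshaft for bead-spring) with weight 0.6 and pivot with 0.4.
    Multiple chains additionally get chain translations with weight 0.2
    (other weights renormalized) to sample the void space of the box.
    """
    bond = spec.bond_length
    if spec.model_kind == BEAD_STICK:
        local = [MoveSpec("crankshaft", math.pi / 2, 0.6)]
    else:
        local = [MoveSpec("local-displacement", 0.25 * bond, 0.3),
                 MoveSpec("crankshaft", math.pi / 2, 0.3)]
    mix = local + [MoveSpec("pivot", 1.0, 0.4)]
    if n_chains > 1:
        amp = 0.5 * (box if box else 4.0 * bond)
        mix = [MoveSpec(m.move_kind, m.amplitude, 0.8 * m.weight) for m in mix]
        mix.append(MoveSpec("chain-translation", amp, 0.2))
    total = sum(m.weight for m in mix)
    return [MoveSpec(m.move_kind, m.amplitude, m.weight / total) for m in mix]


@dataclass
class Proposal:
    """Trial update: changed-bead indices and their new coordinates."""

    indices: np.ndarray        # contiguous bead indices that move
    new_positions: np.ndarray  # (len(indices), 3)
    symmetric: bool = True     # all built-in proposals have Hastings ratio 1


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    ux, uy, uz = u
    c, s = math.cos(angle), math.sin(angle)
    omc = 1.0 - c
    return np.array([
        [c + ux * ux * omc, ux * uy * omc - uz * s, ux * uz * omc + uy * s],
        [uy * ux * omc + uz * s, c + uy * uy * omc, uy * uz * omc - ux * s],
        [uz * ux * omc - uy * s, uz * uy * omc + ux * s, c + uz * uz * omc],
    ])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def propose(conf: Conformation, mspec: MoveSpec,
            rng: np.random.Generator) -> Proposal:
    """Draw a symmetric trial move of the given kind on a random chain.

    Bond-constraint violations of the bead-spring model are allowed at the
    proposal stage; the FENE infinite-energy sentinel rejects them.
    """
    N = conf.n_per_chain
    c = int(rng.integers(conf.n_chains))
    cs = c * N
    pos = conf.positions
    kind = mspec.move_kind
    A = mspec.amplitude

    if kind == "local-displacement":
        k = cs + int(rng.integers(N))
        disp = rng.uniform(-A, A, size=3)
        return Proposal(np.array([k]), pos[k] + disp)

    if kind == "crankshaft":
        k = cs + int(rng.integers(N))
        angle = rng.uniform(-A, A)
        if k == cs:
            axis, point = _random_unit(rng), pos[k + 1]
        elif k == cs + N - 1:
            axis, point = _random_unit(rng), pos[k - 1]
        else:
            axis = pos[k + 1] - pos[k - 1]
            if np.linalg.norm(axis) < 1e-12:
                axis = _random_unit(rng)
            point = pos[k - 1]
        Rm = _rotation_matrix(axis, angle)
        newp = point + Rm @ (pos[k] - point)
        return Proposal(np.array([k]), newp[None, :])

    if kind == "pivot":
        if N < 3:
            raise ValueError("pivot requires chains of at least 3 beads")
        p = cs + 1 + int(rng.integers(N - 2))
        idx = np.arange(p + 1, cs + N)
        axis = _random_unit(rng)
        angle = rng.uniform(-A, A)
        Rm = _rotation_matrix(axis, angle)
        newp = pos[p] + (pos[idx] - pos[p]) @ Rm.T
        return Proposal(idx, newp)

    # chain-translation
    idx = np.arange(cs, cs + N)
    disp = rng.uniform(-A, A, size=3)
    return Proposal(idx, pos[idx] + disp)


def apply_proposal(conf: Conformation, prop: Proposal) -> None:
    conf.positions[prop.indices] = prop.new_positions
    if conf.box is not None:
        conf.rewrap()


def metropolis_accept(dEp: float, weight, rng: np.random.Generator,
                      ep_old: float | None = None) -> bool:
    """Metropolis acceptance for a symmetric proposal.

    ``weight`` is either an inverse temperature ``beta`` (canonical mode,
    accept with ``min(1, exp(-beta dEp))``) or a
    :class:`semiflex.sampling.WeightTable` (generalized mode, accept with
    ``min(1, W(Ep') / W(Ep))``; ``ep_old`` is then required).  Non-finite
    ``dEp`` (bond sentinel, bead overlap) is always rejected.
    """
    if not np.isfinite(dEp):
        return False
    from .sampling import WeightTable  # local import to avoid a cycle
    if isinstance(weight, WeightTable):
        if ep_old is None:
            raise ValueError("generalized acceptance needs the current Ep")
        lw_old = weight.lookup(ep_old)
        lw_new = weight.lookup(ep_old + dEp)
        if not np.isfinite(lw_new):
            return False
        arg = lw_new - lw_old
    else:
        arg = -float(weight) * dEp
    return bool(arg >= 0.0 or rng.random() < math.exp(arg))
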