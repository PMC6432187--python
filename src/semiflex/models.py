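"""Coarse-grained polymer models with short-range attraction and bending stiffness.

Two off-lattice homopolymer models are supported, both built from linearly
connected beads:

* **bead-stick** -- rigid bonds of length ``rb`` (default 1); all non-bonded
  bead pairs interact through a truncated-and-shifted Lennard-Jones
  potential with ``sigma = eps = 1``.
* **bead-spring** -- finitely-extensible nonlinear elastic (FENE) bonds with
  ``r0 = 0.7``, ``R = 0.3``, ``K = 40`` and Lennard-Jones interactions
  between non-bonded beads only, with ``sigma = 2**(-1/6) * r0`` so the LJ
  minimum coincides with the equilibrium bond length.

Semiflexibility enters through a worm-like-chain bending penalty
``kappa * (1 - cos(theta))`` per interior bond angle.  Energies are measured
in units of the LJ well depth ``eps`` and we set ``kB = 1`` throughout, so
temperatures are dimensionless.

The total potential energy of a conformation is

    Ep = E_LJ + kappa * E_bend + E_FENE

where ``E_bend`` is the *unmultiplied* sum of ``(1 - cos(theta))`` terms.
Keeping the bending sum separate from ``kappa`` lets the two-dimensional
energy histogram p(E_LJ, E_bend) be built from a single run.

Bonded pairs are excluded from E_LJ in both models.  In the bead-stick model
bonded pairs sit at the fixed distance ``rb`` and would contribute only the
constant ``(N-1) * V_LJ_shifted(rb)`` per chain; excluding them shifts all
energies by that constant, which cancels in sampling and analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import kernels

BEAD_STICK = "bead-stick"
BEAD_SPRING = "bead-spring"

#: tolerance for the rigid-bond invariant of the bead-stick model
BOND_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Interaction parameters of one of the two polymer models.

    Parameters left as ``None`` are filled with the model's standard values
    (see module docstring).  All lengths are in units of the LJ length scale
    of the respective model, energies in units of ``eps``.
    """

    model_kind: str = BEAD_STICK
    eps: float = 1.0          # LJ well depth (energy scale)
    kappa: float = 0.0        # bending stiffness (energy)
    sigma: float | None = None  # LJ length
    rc: float | None = None     # LJ cutoff; potential shifted to 0 there
    rb: float = 1.0           # fixed bond length (bead-stick)
    K: float = 40.0           # FENE spring constant (energy / length^2)
    R: float = 0.3            # FENE half-width (length)
    r0: float = 0.7           # FENE equilibrium bond length (length)

    def __post_init__(self) -> None:
        if self.model_kind not in (BEAD_STICK, BEAD_SPRING):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.sigma is None:
            sigma = 1.0 if self.model_kind == BEAD_STICK else 2 ** (-1 / 6) * self.r0
            object.__setattr__(self, "sigma", sigma)
        if self.rc is None:
            object.__setattr__(self, "rc", 2.5 * self.sigma)
        if not self.rc > self.sigma:
            raise ValueError("LJ cutoff rc must exceed sigma")
        if self.R <= 0:
            raise ValueError("FENE half-width R must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def kind_id(self) -> int:
        return kernels.KIND_STICK if self.model_kind == BEAD_STICK else kernels.KIND_SPRING

    @property
    def lj_shift(self) -> float:
        """Value of the unshifted LJ potential at the cutoff."""
        sr6 = (self.sigma / self.rc) ** 6
        return 4.0 * self.eps * (sr6 * sr6 - sr6)

    @property
    def bond_length(self) -> float:
        """Equilibrium / fixed bond length of the model."""
        return self.rb if self.model_kind == BEAD_STICK else self.r0

    @property
    def rn(self) -> float:
        """Equilibrium non-bonded contact distance (LJ minimum) 2^(1/6) sigma."""
        return 2 ** (1 / 6) * self.sigma

    def with_kappa(self, kappa: float) -> "ModelSpec":
        return replace(self, kappa=kappa)

    def kernel_params(self, box: float) -> tuple:
        """Scalar parameter tuple consumed by the jitted kernels."""
        return (
            self.kind_id, self.eps, self.sigma, self.rc,
            self.kappa, self.K, self.R, self.r0, float(box),
        )


def bead_spring_spec(kappa: float = 0.0, **kw) -> ModelSpec:
    return ModelSpec(model_kind=BEAD_SPRING, kappa=kappa, **kw)


def bead_stick_spec(kappa: float = 0.0, **kw) -> ModelSpec:
    return ModelSpec(model_kind=BEAD_STICK, kappa=kappa, **kw)


# ---------------------------------------------------------------------------
# pair / bond potentials
# ---------------------------------------------------------------------------

def lj_pair_energy(r: float, spec: ModelSpec, shifted: bool = True) -> float:
    """Truncated (and by default shifted) Lennard-Jones pair energy.

    ``4 eps [(sigma/r)^12 - (sigma/r)^6] - V_LJ(rc)`` for ``r < rc`` and 0
    beyond the cutoff; the shift makes the potential continuous at ``rc``.
    """
    if not np.isfinite(r) or r <= 0.0:
        raise ValueError(f"pair distance must be positive and finite, got {r}")
    if r >= spec.rc:
        return 0.0
    sr6 = (spec.sigma / r) ** 6
    v = 4.0 * spec.eps * (sr6 * sr6 - sr6)
    return v - spec.lj_shift if shifted else v


def bend_energy(theta: float, kappa: float) -> float:
    """Worm-like-chain bending penalty ``kappa * (1 - cos theta)``.

    ``theta`` is the angle between successive bond vectors; the cosine is
    clamped against roundoff so the result is always in ``[0, 2 kappa]``.
    """
    c = min(1.0, max(-1.0, math.cos(theta)))
    return kappa * (1.0 - c)


def fene_bond_energy(r: float, spec: ModelSpec) -> float:
    """FENE bond energy ``-(K/2) R^2 ln(1 - ((r - r0)/R)^2)``.

    Returns ``inf`` (move-rejection sentinel) outside the open interval
    ``(r0 - R, r0 + R)`` -- the bond is finitely extensible.
    """
    x = (r - spec.r0) / spec.R
    arg = 1.0 - x * x
    if arg <= 0.0:
        return math.inf
    return -0.5 * spec.K * spec.R ** 2 * math.log(arg)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimal_image(delta: np.ndarray, L: float) -> np.ndarray:
    """Map each displacement component into ``[-L/2, L/2)``.

    Used for inter-chain pair distances and the phase-separation parameter;
    bond vectors are never minimal-imaged.
    """
    if L <= 0:
        raise ValueError("box edge must be positive")
    d = np.asarray(delta, dtype=float)
    return d - L * np.floor(d / L + 0.5)


def box_from_density(N: int, M: int, rho: float) -> float:
    """Cubic box edge for M chains of N beads at number density rho = N M / V."""
    if rho <= 0:
        raise ValueError("density must be positive")
    return (N * M / rho) ** (1 / 3)


# ---------------------------------------------------------------------------
# conformations
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    """Positions of ``M`` chains of ``N`` beads each, optionally in a cubic box.

    Chains occupy contiguous index ranges ``[c*N, (c+1)*N)``.  Chains are
    stored *unwrapped*: bond vectors are plain coordinate differences.  When
    a box is present the whole chain is kept near the box by rigid centre-of-
    mass re-wrapping; inter-chain distances always use the minimal image.
    """

    positions: np.ndarray          # (N*M, 3) float64
    n_per_chain: int               # N
    n_chains: int = 1              # M
    box: float | None = None       # cubic box edge L, or None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N*M, 3)")
        if self.positions.shape[0] != self.n_per_chain * self.n_chains:
            raise ValueError("positions length does not match N * M")
        if self.box is not None and self.box <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_per_chain * self.n_chains

    @property
    def box_or_zero(self) -> float:
        return 0.0 if self.box is None else float(self.box)

    def chain(self, c: int) -> np.ndarray:
        N = self.n_per_chain
        return self.positions[c * N:(c + 1) * N]

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.n_per_chain,
                            self.n_chains, self.box)

    def bond_lengths(self) -> np.ndarray:
        out = []
        for c in range(self.n_chains):
            ch = self.chain(c)
            out.append(np.linalg.norm(np.diff(ch, axis=0), axis=1))
        return np.concatenate(out) if out else np.empty(0)

    def validate(self, spec: ModelSpec) -> None:
        """Check bond invariants; raise ValueError on violation."""
        bl = self.bond_lengths()
        if spec.model_kind == BEAD_STICK:
            if bl.size and np.max(np.abs(bl - spec.rb)) > BOND_TOL:
                raise ValueError("bead-stick bond length invariant violated")
        else:
            if bl.size and (np.min(bl) <= spec.r0 - spec.R or
                            np.max(bl) >= spec.r0 + spec.R):
                raise ValueError("bead-spring bond outside (r0-R, r0+R)")
        if self.box is not None:
            # dilute-regime contract: a chain must never self-interact across
            # the boundary, guaranteed when its contour length < L/2
            contour = (self.n_per_chain - 1) * (spec.r0 + spec.R
                       if spec.model_kind == BEAD_SPRING else spec.rb)
            if contour >= self.box / 2:
                raise ValueError(
                    f"chain contour length {contour:.3g} exceeds L/2; "
                    "unwrapped-chain storage is invalid at this density")

    def rewrap(self) -> None:
        """Rigidly translate each chain so its centre of mass lies in [0, L)^3."""
        if self.box is None:
            return
        L = self.box
        N = self.n_per_chain
        for c in range(self.n_chains):
            ch = self.chain(c)
            com = ch.mean(axis=0)
            ch -= L * np.floor(com / L)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential-energy components: Ep = elj + kappa * ebend + efene."""

    elj: float      # Lennard-Jones sum (energy)
    ebend: float    # raw Sum(1 - cos theta), dimensionless
    efene: float    # FENE bond sum (energy); 0 for bead-stick
    kappa: float    # stiffness used to form the total

    @property
    def ep(self) -> float:
        return self.elj + self.kappa * self.ebend + self.efene

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.ep))


def total_energy(conf: Conformation, spec: ModelSpec) -> EnergyBreakdown:
    """Exact total potential energy of a conformation.

    LJ sums run over all non-bonded pairs (minimal image for inter-chain
    pairs when a box is present); the bending sum runs over the ``N - 2``
    interior angles of every chain; FENE terms apply to bead-spring bonds.
    Overlapping beads yield a non-finite result rather than an exception.
    """
    elj, ebend, efene = kernels.total_energy_arrays(
        conf.positions, conf.n_per_chain, conf.n_chains,
        *spec.kernel_params(conf.box_or_zero))
    return EnergyBreakdown(elj=elj, ebend=ebend, efene=efene, kappa=spec.kappa)
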