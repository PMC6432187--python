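# Methods

This note documents the models, algorithms and numerical choices behind
`semiflex`: what is simulated, how, with which defaults, and what the
synthetic test conditions do and do not demonstrate.

## Polymer models

Two coarse-grained off-lattice homopolymer models of `M` linear chains of
`N` beads:

* **bead-stick** — rigid bonds of length `rb = 1`; all non-bonded pairs
  interact via a Lennard-Jones potential with `sigma = eps = 1`.
* **bead-spring** — FENE bonds
  `V_FENE(r) = -(K/2) R^2 ln[1 - ((r-r0)/R)^2]` with `r0 = 0.7`,
  `R = 0.3`, `K = 40`, and LJ interactions between non-bonded beads only,
  with `sigma = 2^(-1/6) r0` so that bonded and non-bonded equilibrium
  distances coincide.

Both use the truncated-and-shifted LJ potential
`V(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] - V(rc)` with `rc = 2.5 sigma`,
and the worm-like-chain bending penalty `kappa (1 - cos theta)` per
interior angle.  `kB = 1`, energies in units of `eps`, so temperature is
dimensionless.  With these parameterizations a 40-mer bead-spring chain and
a 28-mer bead-stick chain have the same linear extension `N r0 = 28`; the
bead-stick model's bonded/non-bonded length-scale mismatch
`rn/rb = 2^(1/6) ≈ 1.12` is the feature associated with its stable knotted
phases, which the bead-spring model (`rn/r0 = 1`) lacks.

**Bonded-pair LJ convention.**  Bonded pairs are excluded from the LJ sum
in both models.  For the bead-stick model, where bonded pairs sit at the
fixed distance `rb`, this differs from the all-pairs convention only by the
constant `(N-1) V_shifted(rb)` per chain, which cancels in sampling,
reweighting and all derivatives.

**Periodic boxes.**  Multi-chain systems live in a cubic box of edge
`L = (N M / rho)^(1/3)`.  Chains are stored *unwrapped* (bond vectors are
plain coordinate differences) and each chain is rigidly re-wrapped by its
centre of mass; beads may therefore protrude slightly outside `[0, L)`.
Inter-chain pair distances and the phase-separation parameter use the
minimal-image convention.  This storage is valid only in the dilute regime,
enforced by requiring the chain contour length to be below `L/2`
(`Conformation.validate`).

## Monte Carlo engine

All proposals are symmetric (Hastings ratio 1):

| move | applies to | proposal |
|---|---|---|
| local displacement | bead-spring | bead shift uniform in a cube |
| crankshaft | both | single-bead rotation about the neighbour axis, angle uniform in `[-A, A]`; end beads rotate about a random axis through their neighbour |
| pivot | both | rigid rotation of the tail beyond a random interior bead, axis uniform on the sphere |
| chain translation | multi-chain | rigid shift uniform in a cube |

The bead-stick model forbids local displacements (rigid bonds); its local
move is the crankshaft, which preserves both adjacent bond lengths exactly.
Default mixture: local/crankshaft 0.6 and pivot 0.4 for a single chain;
multi-chain systems reassign 0.2 to chain translations (void-space
sampling).  One sweep is `N*M` elementary proposals; measurements are taken
once per sweep.  Amplitudes may be auto-tuned toward 30–60% acceptance
during equilibration only and are frozen before any measurement, so
detailed balance holds throughout production.

Energy bookkeeping is incremental: each proposal evaluates only the terms
coupling the moved (contiguous, rigidly transformed) bead range to the
rest.  The running energy is resynchronized against a full recomputation
every 20 000 sweeps by default; the suite asserts agreement to 1e-8 after
>1e4 accepted moves with resynchronization disabled.  FENE bond violations
and bead overlaps return an infinite-energy sentinel (rejection), never an
exception, inside the sampling loop.

The inner loop is compiled with numba; the Python-level
`moves.propose`/`metropolis_accept` API implements the same move set as a
readable reference used by the geometry tests.

## Generalized-ensemble sampling

Canonical sampling uses the Metropolis rule `min(1, exp(-beta dEp))`.  The
multicanonical mode replaces the Boltzmann factor with a binned weight
`W(Ep)` (bin width `dE = 0.5 eps` by default) and accepts with
`min(1, W(Ep')/W(Ep))`; proposals leaving the table range are rejected.
Sampling is restricted to the *potential* energy; momentum parts of a full
Hamiltonian would contribute only analytic terms.

**Weight iteration.**  `ln W` is seeded by a temperature-ladder anneal:
short canonical runs at 8 geometrically spaced temperatures between
`t_hot` and `t_min` give points `(⟨Ep⟩_i, beta_i)`; interpolating
`beta(Ep)` and integrating `ln W = -∫ beta dEp` yields a starting table
close to `1/Omega`.  Each iteration then samples under the current table
and applies the accumulated-statistics recursion on nearest-neighbour
log-weight ratios: the pair correction `ln H_k - ln H_{k+1}` is damped by
`g0_k / Σ g0_k` with `g0_k = H_k H_{k+1} / (H_k + H_{k+1})`.  Working on
ratios avoids the stitching constants of bin-wise updates (which can
create artificial traps at coverage boundaries), and the damping makes the
estimate converge as statistics accumulate.

**Convergence.**  The flatness criterion is `min/mean >= 0.5` of the visit
histogram over the target window.  In `beta_max` mode the window is the
covered energy range whose local inverse temperature `-d lnW/dEp` stays
below `beta_max = 1/t_min`, with the additional requirement that coverage
reaches the cold edge (edge slope within 5% of `beta_max`); the weights
then span all temperatures in `[t_min, t_hot]`.  Iterations use a growing
sweep schedule (default 8k → 40k, factor 1.4); non-convergence within
`max_iter` returns the best table flagged `converged=False`.

**Parallel walkers.**  `parallel_muca` runs `k` independently seeded
walkers per iteration and sums their histograms before each update —
statistically equivalent to the serial scheme (`walkers=1` *is* the serial
scheme).  Walkers are executed sequentially in-process; the contract
(independent chains communicating only summed histograms at iteration
boundaries) is what matters for correctness, not the execution vehicle.

**Fixed-total-energy weights.**  `microcanonical_weight` implements
`W(Ep) = (E - Ep)^((Ndof-2)/2)` with `Ndof = 3 N M` momentum degrees of
freedom, zero for `Ep >= E`; `nve_weight_table` materializes it on a grid
so the same generalized-ensemble machinery can sample at fixed total
energy.  Parallel tempering over a temperature ladder (neighbour swaps
with `min(1, exp(dbeta dEp))`) is provided as an alternative for canonical
production.

## Reweighting and errors

Canonical averages at inverse temperature `beta` follow from the ratio
estimator `⟨O⟩ = ⟨O e^{-beta Ep}/W⟩ / ⟨e^{-beta Ep}/W⟩` with log-sum-exp
stabilization (results are invariant under constant shifts of `ln W` to
1e-12 relative).  The Kish effective sample size defines the trustworthy
temperature window; estimates with ESS < 100 are flagged.  Thermal
derivatives use `d⟨O⟩/dT = beta^2 (⟨O Ep⟩ - ⟨O⟩⟨Ep⟩)`.  Errors for
arbitrary nonlinear statistics come from contiguous-block jackknife
resampling (20 blocks by default), bias-corrected; contiguous blocks
absorb autocorrelation.

## Observables

Per conformation: squared radius of gyration `Σ(r_i - r_cm)^2 / N` and
end-to-end distance per chain (averaged over chains); for `M >= 2` the
end-to-end correlation parameter `CR = (2/M(M-1)) Σ_{i<j} (û_i·û_j)^2`
(1 for aligned bundles, 1/3 for uncorrelated chains; chains with
vanishing end-to-end vector are excluded pairwise) and the
phase-separation parameter `Gamma2 = (1/2M^2) Σ_{i,j} |r_cm^i - r_cm^j|^2`
over ordered pairs with minimal-image distances.  The double sum over
ordered pairs is fixed by the two-chain limit `Gamma2 = d^2/4`.  The 2D
histogram `p(E_LJ, E_bend)` (with the bending sum stored unmultiplied by
`kappa`) and its projection onto `E = E_LJ + kappa E_bend` expose phase
coexistence that the 1D energy distribution can hide when the two phases
lie on an anti-diagonal.

## Microcanonical analysis

Flat-histogram production gives `ln Omega = ln H - ln W` bin-wise
(additive constant fixed at the maximum).  `beta(Ep) = d ln Omega/dEp` is
taken by centred differences on the staggered boundary grid and
`gamma = d beta/dEp` back on bin centres, after Gaussian smoothing of
`ln Omega` (default sigma = 2 bins, recorded in the profile).  A positive
`gamma` peak (back-bending of `beta`) classifies a finite-size transition
as first-order-like; a negative peak as second-order-like.  The peak must
exceed 3x the median `|gamma|` of the high-energy tail (noise floor).
Analysis is restricted to the contiguous block of bins with at least 20
production visits, with 8% of the block trimmed at each edge where finite
differences and smoothing are boundary-contaminated.

## Scaled-down study conditions

The stiffness crossover of the collapse transition is measured on the
bead-spring 40-mer.  Per stiffness: hot canonical pilot for the upper
energy bound, weight iteration in `beta_max` mode over the temperature
window `[0.55, 2.5]` (which brackets the collapse/folding region of this
chain), then 250k production sweeps continued from the iteration's end
state.  The end state typically sits on the low-energy branch, and
unfolding upward crosses the transition bottleneck far more readily than
folding from a hot start, so both branches get sampled.  Classification
uses pointwise `gamma` error bars from a moving-block bootstrap of the
production series and is localized around the canonical transition
(`CV` peak mapped to its mean energy).  The crossover stiffness is
estimated from signed `gamma` peaks on a coarse grid with one bracket
refinement, reported as the bracket midpoint.

**Known desk-scale limitation.**  Near the crossover the back-bend of
`beta(Ep)` is shallow while round trips of a single flat-histogram walker
through the folding bottleneck are rare (of order one per 10^5-10^6
sweeps measured at `kappa = 8`): the density-of-states estimate across the
barrier then rests on very few crossing events, and the sign of the
transition `gamma` peak fluctuates between realizations for
`kappa ~ 6-10`.  The flexible side (`kappa <~ 4`, clear negative peak) is
robust; the stiff side becomes reliable only with far more statistics (or
better barrier-crossing moves).  The crossover estimate at these problem
sizes is therefore biased toward stiffer values and can land anywhere in
the stiff half of its bracket; published values for this system come from
runs with orders of magnitude more statistics.

## Knot identification

Open chains are closed virtually: both endpoints extend radially from the
chain's centre of mass to a sphere of 3x the maximal bead-COM distance and
join through a far apex (3 added vertices, deterministic).  The closed
polygon is projected orthogonally to a seed-derived random direction;
non-generic projections (vertex hits, height ties, singular Alexander
matrices) are detected and retried with fresh directions.  Crossings give
the Alexander matrix (arcs between consecutive undercrossings; rows
`t x_in + (1-t) x_over - x_out` for positive crossings and the
`t`-multiplied mirror rule for negative ones); one row and column are
deleted and `|Delta(t) Delta(1/t)|` at `t = -1.1` is evaluated via
`slogdet`.  The product form cancels the `±t^k` normalization ambiguity
and is mirror-invariant — chirality is intentionally not resolved.
Classification matches against a table computed from the standard
Alexander polynomials of prime knots to 8 crossings at relative tolerance
1e-3, safely below half the closest table gap (4_1 vs 5_1, ~1.5%).
Near a knotting transition, open-chain knot assignment can be sensitive to
the closure prescription; the radial closure was chosen for determinism
and minimal spurious crossings and is validated on parametric torus-knot
fixtures at 40–400 vertices.

## Synthetic fixtures: what they do and do not cover

The fixture module generates rods, hairpins, random coils, aligned and
random bundles, parametric `(p,q)` torus knots and a two-level toy system
with closed-form thermodynamics.  These exercise exact limits (CR = 1 and
1/3; rod `R_gyr^2 = (N^2-1)/12`; torus-knot topology) and oracle
statistics, but they do not emulate rugged low-temperature landscapes,
finite sampling of rare first-order coexistence, or closure-sensitive
marginal knots; passing the suite therefore validates the estimators and
bookkeeping, not the exhaustiveness of low-temperature sampling for large
stiff systems.

## Known limitations

* Single-process execution; walker and replica parallelism are contracts,
  not OS-level parallelism.
* The muca window logic assumes `beta(Ep)` is, apart from finite-size
  back-bending, decreasing in `Ep`; exotic densities of states with
  multiple deep convex regions may need an explicit energy range.
* Knot chirality and composite knots are not distinguished (Alexander
  polynomial limitations); knot localization along the chain is out of
  scope.
* Lattice models, torsional potentials, Wang-Landau-family schedules and
  multi-histogram (WHAM) combination are intentionally not implemented.
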