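# semiflex

Generalized-ensemble Monte Carlo for dilute, self- and mutually-attractive
**semiflexible polymers**: single-chain collapse and folding, stable knotted
phases, and multi-chain aggregation into amorphous clusters or bundles.

`semiflex` is aimed at researchers studying the statistical mechanics of
coarse-grained polymer models who need, in one consistent toolkit:

* two standard off-lattice models — a **bead-stick** chain (rigid bonds,
  `rb = 1`, LJ `sigma = eps = 1`) and a **bead-spring** chain (FENE bonds,
  `r0 = 0.7`, `R = 0.3`, `K = 40`, `sigma = 2^(-1/6) r0`) — both with
  truncated-shifted Lennard-Jones attraction (`rc = 2.5 sigma`) and a
  worm-like-chain bending energy `kappa (1 - cos theta)`, with optional
  cubic periodic boxes (minimal image) at density `rho = N M / V`;
* **multicanonical (flat-histogram) sampling** with an accumulated ratio
  recursion for the weights `W(Ep) ~ 1/Omega(Ep)`, optional independent
  parallel walkers, a fixed-total-energy (`NVE`) generalized weight
  `(E - Ep)^((Ndof-2)/2)`, and parallel tempering;
* **canonical reweighting** `<O>_beta = <O e^{-beta Ep}/W> / <e^{-beta Ep}/W>`
  with jackknife errors, thermal derivatives
  `d<O>/dT = beta^2 (<O Ep> - <O><Ep>)` and transition-line peak scans;
* **microcanonical analysis**: `S(Ep) = ln Omega(Ep)`,
  `beta(Ep) = dS/dEp`, `gamma(Ep) = dbeta/dEp`, with finite-size
  transition-order classification — back-bending of `beta` (positive
  `gamma` peak) is first-order-like, a negative `gamma` peak
  second-order-like;
* aggregation order parameters: the end-to-end correlation
  `CR = (2/M(M-1)) sum_{i<j} (u_i . u_j)^2` (1 for bundles, 1/3 for
  uncorrelated chains) and the phase-separation parameter `Gamma2`;
* **knot detection** for open chains: deterministic radial closure,
  generic-direction projection, and the Alexander-polynomial product
  `Delta_p = |Delta(t) Delta(1/t)|` at `t = -1.1`, classified against the
  prime-knot table up to 8 crossings (`0_1`, `3_1`, `4_1`, `5_1`, ...,
  `8_19`).

The Monte Carlo inner loop is numba-compiled; runs are deterministic given
their seeds.

## Worked example

Collapse analysis of a flexible bead-spring 13-mer — iterate multicanonical
weights, run flat-histogram production, and reweight to canonical averages
at any temperature in the covered window:

```python
import semiflex as sf
from semiflex.fixtures import initial_conformation

spec = sf.bead_spring_spec(kappa=0.0)
conf = initial_conformation(spec, N=13, seed=1)

muca = sf.iterate_muca_weights(conf, spec, -45.0, 32.0, de=0.5, seed=3,
                               beta_max=1.0, t_hot=3.0)
series, run = sf.muca_production(muca.conf, spec, muca.weights,
                                 150_000, seed=4)
print(f"converged={muca.converged} after {muca.n_iterations} iterations; "
      f"production flatness {run.hist.flatness(muca.window):.2f}")
for T in (1.0, 2.0, 3.0):
    e = sf.reweight(series, 1.0 / T, series.ep)
    rg = sf.reweight(series, 1.0 / T, "rg2")
    print(f"T={T}: <Ep> = {e.value:+.2f}  <Rgyr^2> = {rg.value:.2f} "
          f"(ESS {e.ess:.0f})")
```

Output:

```
converged=True after 15 iterations; production flatness 0.60
T=1.0: <Ep> = -6.07  <Rgyr^2> = 1.00 (ESS 23642)
T=2.0: <Ep> = +1.50  <Rgyr^2> = 1.59 (ESS 28452)
T=3.0: <Ep> = +4.25  <Rgyr^2> = 1.78 (ESS 32167)
```

One multicanonical run covers the whole temperature window: the chain is
collapsed at `T = 1` (small radius of gyration, negative energy) and
swollen at `T = 3`; the effective sample size shows how much statistics
supports each temperature.

Knot identification of a parametric cinquefoil:

```python
from semiflex.fixtures import torus_knot
res = sf.identify(torus_knot(2, 5, 120), seed=1)
print(res.label, round(res.delta_p, 3))   # 5_1 25.457
```

A command-line interface mirrors the library
(`semiflex simulate | iterate-weights | reweight | analyze-micro | knots |
fixtures | scan`); trajectories are extended XYZ, tables TSV, checkpoints
HDF5.

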