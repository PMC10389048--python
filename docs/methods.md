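# Methods

## Model

The package models intracellular glucose `[Glci]` in a fermenting yeast
cell as a single ODE balancing facilitated glucose influx (`Vin`) against
hexokinase consumption (`Vhk`):

```
d[Glci]/dt = (Vin − Vhk) / volume
Vin = volume · (Vm1 − KilG6P · [G6P])
Vhk = volume · Vm2 / (1 + Km2Glc/[Glci] + Km2ATP/[ATP]
                        + Ks2Glc · Km2ATP / ([Glci] · [ATP]))
```

Assumptions:

* `[G6P]` and `[ATP]` are boundary species held constant (defaults 1.0);
  the glucose subsystem is cut out of the larger glycolysis network.
* A single, well-mixed cytoplasmic compartment (`volume`, default 1.0).
  The volume cancels between the rates and the concentration balance.
* Concentrations are non-negative; the integrator clamps the state at 0
  and warns if clamping occurred.
* The influx rate is a linearized carrier law (`Vm1` minus product
  inhibition by G6P); it can be negative, representing net efflux.

### Reduced form and structural non-identifiability

Writing `G = [Glci]` and multiplying the `Vhk` denominator through by
`G`, the ODE becomes

```
dG/dt = a − vm2 · G / (A·G + B)
a  = Vm1 − KilG6P·[G6P]
A  = 1 + Km2ATP/[ATP]
B  = Km2Glc + Ks2Glc · Km2ATP/[ATP]
```

Dividing numerator and denominator by `A` shows the trajectory depends on
only **three** combinations of the six parameters: `a`, `vm2/A`, `B/A`
(`beefit.model.reduced_rate_constants` exposes them). The SSE zero set of
a noiseless instance is therefore a curved 3-dimensional manifold inside
the 6-dimensional box, and no individual parameter is identifiable from a
single `[Glci]` series. `beefit.evaluation.profile_identifiability`
verifies this empirically per instance: each parameter is fixed at ±20 %
of its true value and the remaining five are re-optimized (log-space
Nelder–Mead, two restarts); a parameter is flagged identifiable only if
the profile SSE rises meaningfully above the all-free floor. On the
default instance the identifiable set is empty, as the algebra predicts.

## Default problem instance

`beefit.synthetic.default_problem` fixes the study conditions:

| quantity | default | rationale |
|---|---|---|
| truth (Vm1, KilG6P, Vm2, Km2Glc, Km2ATP, Ks2Glc) | 1.5, 0.1, 2.0, 0.5, 0.2, 0.3 | order-of-magnitude plausible Michaelis/inhibition constants (mM, mM/s scale) producing a well-curved relaxation of `[Glci]` from 1.0 toward its steady state |
| time grid | 201 points on [0, 100] s | resolves the transient and a long quasi-steady tail |
| environment | volume = G6P = ATP = Glci(0) = 1.0 | dimensionless reference condition |
| noise | zero-mean Gaussian, σ = 1 % of the clean dynamic range | mimics relative measurement error of metabolite assays; σ = 0 gives the noiseless variant |
| initial guess | truth × log-uniform factor in [1/3, 3] per parameter | a plausibly wrong literature guess |
| search bounds | guess/10 … guess×10 | two decades around the guess, the usual ignorance window for kinetic constants |

These defaults were chosen once, before any optimizer was run, and are
not tuned to make benchmarks pass.

What the synthetic data emulate: additive, homoscedastic, independent
Gaussian measurement noise on a single observed species sampled on a
regular grid. What they do **not** emulate: biological replicate
variability, systematic calibration error, correlated or multiplicative
noise, missing samples, multi-species read-outs, or model mismatch (the
generating model is the fitted model).

## Objective and numerics

The objective is the plain SSE between the simulated and observed series
on the shared grid. Two integrators are used:

* **Public simulation** (`beefit.model.simulate`): scipy `solve_ivp`
  RK45 with `rtol = 1e-8`, `atol = 1e-10`. The right-hand side is
  evaluated in the rational reduced form above, which is regular at
  `G = 0` (the raw `Vhk` expression has `1/G` singularities).
* **Fast objective** (`beefit.objective.build_objective`): a
  numba-compiled fixed-step classical RK4 with step `dt_max = 0.05` s. It
  is orders of magnitude faster than the adaptive integrator, making the
  multi-hundred-run benchmark protocols feasible; the test suite verifies
  its agreement with the adaptive reference on the default instance.

Fitness for the roulette selection uses the standard transform
`fit = 1/(1+f)` for `f ≥ 0` and `1 + |f|` otherwise (the objective here
is a non-negative SSE, so the second branch is defensive).

## Artificial Bee Colony

Canonical ABC with `SN` food sources (= employed bees = onlooker bees):

* **Initialization**: uniform in the box, `x = lower + U(0,1)·(upper−lower)`;
  failed objective evaluations are retried up to a cap.
* **Neighbor move**: `v_d = x_{i,d} + φ·(x_{i,d} − x_{k,d})`, with one
  random dimension `d`, random partner `k ≠ i`, `φ ~ U(−1, 1)`, clipped
  to the bounds. Greedy selection keeps the move only on **strict**
  improvement; ties reject the candidate and increment the trial counter,
  so exhausted sources still age toward abandonment.
* **Onlookers**: roulette selection with `p_i = fit_i / Σ fit`,
  recomputed after every placement so improvements propagate within the
  phase.
* **Scouts**: at most one per cycle; among sources with
  `trial ≥ limit` the one with the largest trial count (lowest index on
  ties) is redrawn uniformly. The source currently holding the best
  objective is exempt from abandonment, so the best-so-far solution is
  never discarded: without this exemption the roulette concentrates
  nearly all onlookers on the single best source, its trial counter races
  past the limit, and the scout would delete the best solution every few
  cycles.
* Defaults `SN = 40`, `limit = 30`, `200` cycles give an evaluation
  budget of `SN + 2·SN·cycles = 16 040` plus scout redraws.

Determinism: one `numpy` Generator per run with a documented draw order;
equal seeds give bit-identical results.

## Baselines

Both baselines are capped at the same evaluation budget as ABC.

* **Simulated annealing**: Metropolis acceptance, geometric cooling
  (rate 0.95), 20 proposals per temperature, Gaussian steps with scale
  0.1 of the bound width, initial temperature set to the objective at the
  start point so initial acceptance is moderate regardless of scale.
* **Nelder–Mead simplex**: standard coefficients (reflection 1,
  expansion 2, contraction 0.5, shrink 0.5), candidates clipped to the
  bounds, random in-box start derived from the seed.

## Evaluation metrics

For `N` runs against a reference `y` (true parameters, or the observed
series): `e = Σ_runs Σ_components (y − ŷ)²`, average error rate
`A = e/N`, and `STD = sqrt(e/N)` (default `rms` mode; a `literal` mode
with `STD = e/N` is provided as a documented alternative reading).
Because the parameter vector is non-identifiable, the headline comparison
tables are computed in **time-series space** (distance between the
best-fit trajectory and the data); parameter-space tables are also
produced for completeness.

## Open design decisions and limitations

* **Coordinate moves stall on curved valleys.** The canonical
  one-dimension-at-a-time move makes ABC a randomized coordinate descent
  near convergence. On this model's curved 3-D optimal manifold it
  reliably stalls at coordinate-wise minima — the noiseless recovery
  quantities reported by `scripts/acceptance.py` show the final SSE
  plateauing orders of magnitude above zero — even though the same
  implementation solves separable control landscapes like the sphere with
  ease. Perturbing all dimensions at once (`perturb_all_dims=True`) is
  provided but empirically worse here. A rotation-invariant move or a
  local-polish hybrid would fix this and is deliberately out of scope.
* **Ranking is instance-dependent.** At matched budgets the simplex
  either converges very well or fails catastrophically depending on its
  start; medians and means can therefore order the algorithms
  differently. Both spaces and both statistics are reported rather than a
  single verdict.
* The `STD` definition ambiguity is handled by the explicit
  `mode={"rms","literal"}` switch rather than silently choosing one.
* The SBML reader (`beefit.sbml`) is a minimal lxml-based subset
  (compartments, species, global parameters, reactions, MathML kinetic
  laws rendered to infix) intended for inspecting curated models, not a
  validating parser.
* Single observed species, single compartment, constant boundary
  metabolites; no fitting of initial conditions or noise variance.

No empirical claim in this document goes beyond quantities computed by
the test suite or `scripts/acceptance.py`.
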