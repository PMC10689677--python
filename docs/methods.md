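# Methods

This note documents the models, algorithms, defaults and design choices
behind `inferode`, and what the built-in synthetic fixtures do and do not
establish about real data.

## Problem definition

A problem is an ordered list of parameters, each with an id, a scale
(`lin` or `log10`), bounds, a linear-scale nominal value, an estimate
flag and an optional prior, bound to an objective. All optimization,
profiling and sampling happens on the **estimation scale** (base-10
logarithm for `log10` parameters) and on the **free** subspace; fixed
values are re-inserted before every objective evaluation. Bounds are
stored and enforced on the estimation scale; tables supply them on the
linear scale and they are converted on load, matching the PEtab
convention.

Startpoints are sampled inside the free bounds either i.i.d. uniformly or
by Latin hypercube (the default): per dimension, one uniform draw inside
each of `n_starts` equal-width strata with an independent stratum
permutation — unbiased coverage, better space-filling than i.i.d. sampling
at small `n`. Sampling is a pure function of (bounds, n, method, seed).

## Objectives and derivatives

Objectives return a negative log-likelihood, negative log-posterior, or
least-squares value (`½ Σ r²`, consistent with its residual vector to
round-off), with optional gradients. Non-finite values propagate as +inf so
optimizers survive infeasible trial points; evaluation counters are part of
the contract and stored with results.

Finite differences support forward, backward and central schemes. At
bound-adjacent points a central scheme degrades automatically to the
feasible one-sided scheme, so the objective is never evaluated outside
bounds. Adaptive step selection evaluates the central-difference
derivative on a decreasing ladder (1e-1 … 1e-8 by default) and picks the
larger step of the consecutive pair minimizing |d(hₖ) − d(hₖ₊₁)| — a
successive-difference stability criterion. Differences indistinguishable
from round-off (within 1e-9 of the derivative magnitude) count as ties and
break toward the larger step; this matters on exactly quadratic functions,
where every step is equally good and the cheapest robust choice is the
largest.

Priors (uniform, normal, log-normal) can apply on the estimation or the
linear scale; the posterior aggregation adds negative log prior densities
with the appropriate change of variables for the gradient. A uniform prior
inside bounds shifts the objective by a constant and leaves optimizer
trajectories unchanged.

## ODE backend

Built-in models (conversion reaction A ⇌ B; exponential decay) carry
hand-coded state and parameter Jacobians. Simulation uses an adaptive
stiff/non-stiff solver (LSODA) with rtol = 1e-8, atol = 1e-10 — tight
because forward sensitivities are integrated jointly via the augmented
system `ṡ = (∂f/∂x)s + ∂f/∂θ` and gradient accuracy inherits integration
error. Finite differences remain available as an independent cross-check;
the test suite verifies sensitivity-based gradients against central FD at
relative tolerance 1e-5.

Observables are linear read-outs of the state. Affine observation layers
`b + s·y` and the noise model live in the likelihood, not the model: the
Gaussian negative log-likelihood per measurement row resolves offset,
scaling and noise sd each either to a constant or to a parameter-vector
entry, and the gradient chains through simulation sensitivities, the
observation parameters, and the noise terms, then through the estimation
scales.

### Synthetic-data generator

`generate_synthetic_data` simulates a model and adds i.i.d. Gaussian noise
N(0, σ²) per observable and time point; σ = 0 yields noise-free tables.
The default conversion-reaction fixture uses k1 = 0.06, k2 = 0.08,
x(0) = (1, 0), ten equispaced times on [0, 30] and σ = 0.02 — informative
dynamics inside the window and a realistic ~2% noise level for this scale
of observable. The relative-data variant scales the second observable by
s = 2.5 and estimates per-observable noise sds. What the generator does
**not** emulate: outliers and non-Gaussian noise, missing observations,
time-point-dependent noise, model misspecification, and multi-condition
designs beyond constant parameter overrides. Passing tests therefore
demonstrate algorithmic correctness under the assumed noise model, not
robustness to its violation.

## PEtab-subset bundles

A YAML index references four TSV tables (parameters, observables,
measurements, conditions) plus a built-in model registry id in place of an
SBML file. Supported columns: `parameterId, parameterScale ∈ {lin,log10},
lowerBound, upperBound, nominalValue, estimate` (+ optional
`hierarchical` flag); observable formulas restricted to affine read-outs
(`obs`, `s * obs`, `b + s * obs`); noise formulas a constant or a
parameter id; condition tables provide constant parameter overrides only.
Validation returns all violations (dangling ids, bound order, duplicate
ids, negative times) as data, not exceptions. Files that fit the subset
are bit-compatible with PEtab tools.

## Multi-start optimization

One concrete local optimizer ships: bound-constrained L-BFGS-B behind the
`local_minimize` contract (the contract, not the library, is normative).
Defaults: maxiter 1000, ftol 1e-14, gtol 1e-9 — tight termination so that
independent formulations of the same problem (hierarchical vs joint) agree
to ~1e-6 in optimal value. Objectives without native gradients fall back
to central finite differences (step 1e-6). Non-finite trial values are fed
to the line search as a large finite sentinel (1e100) because L-BFGS-B
does not digest infinities. A returned point is never worse than its
start. Runs sort by (ok, fval, start_index) — failed starts last, stable
ties — and the waterfall is the ranked list of successful final values.
The default start count is 100 (configurable); the acceptance benchmarks
use 20, ample for the 2-D fixtures.

## Hierarchical inner problem

Grouping derives from the per-row parameter sources of the joint
objective: rows sharing an inner offset/scaling pair form one group per
role, rows sharing an inner σ another. With a shared σ per scaling group
the weighted least-squares inner problem reduces to unweighted, so the
solve order (b, s) then σ is exact without iteration:

- s* = Σ d·y / Σ y² (scaling only),
- (b*, s*) from the 2×2 normal equations (offset + scaling),
- σ* = √(mean squared residual), floored at 1e-10 before log terms to
  avoid −∞ likelihoods at zero residuals (the floor never activates on
  fixtures with σ_true ≥ 1e-3).

Degenerate groups (all-zero simulation, singular normal equations) give
+inf with a diagnostic. Outer gradients use finite differences; the
envelope-theorem chain rule through the inner optima is a possible
extension, not needed for correctness. Sharing granularity is per
observable; per-condition sharing is an extension point. Ordinal or
censored data are out of scope.

## Profile likelihood

From the best run, each parameter is walked down and up with adaptive
steps: grow ×2 when the last objective change is below half the target
(0.2), shrink ×0.5 above twice the target, clipped to [1e-4, 1] on the
estimation scale; an overshooting step is additionally retried at half
size so the cutoff region is bracketed finely — this keeps interpolated
interval endpoints within ~0.1% on quadratic objectives. Each point
re-optimizes all remaining parameters warm-started from its neighbor.
Legs stop below ratio 0.03 (beyond the 95% cutoff 0.1465), at a bound, or
at 100 points. Interval endpoints interpolate linearly in log-ratio —
near-exact where the objective is locally quadratic; a side that hits a
bound before the threshold is flagged open. The profile posterior is the
same machinery on a negative-log-posterior objective.

## Sampling

Adaptive Metropolis: Gaussian random walk whose covariance tracks the
chain (stochastic approximation with γ_t = (t+1)^-0.51, regularization
1e-10·I) and whose log scale moves by γ_t(α − 0.234), with α the
Metropolis acceptance **probability** (lower-variance signal than the
binary indicator). Initial covariance: diag((bound range / 20)²).
Out-of-bounds proposals are rejected (truncated posterior). Adaptation can
be frozen after a configurable iteration; decay 0.51 lies inside the
(0.5, 1] validity range of such schemes.

Parallel tempering runs K chains (default 5) at inverse temperatures
β, geometrically initialized with ratio 0.25 and β₁ pinned at 1; each
chain is itself adaptive-Metropolis on the target `exp(−β Λ)`. Every 10
iterations adjacent pairs swap on an alternating even/odd schedule with
acceptance `min(1, exp((βᵢ − βᵢ₊₁)(Λᵢ − Λᵢ₊₁)))`. The ladder adapts in
log-temperature-gap space, `Sᵢ += κ(t)(Aᵢ − Aᵢ₊₁)` with
κ(t) = 1/(t/1000 + 1) and per-pair acceptance estimates smoothed by an
EWMA (memory 0.95), equalizing swap rates while preserving monotonicity;
all chains stay at β > 0 so every chain remains informative. With one
chain the sampler reduces exactly (bit-identically) to adaptive
Metropolis.

One property worth stating plainly: on the 1-D equal-weight bimodal
benchmark (modes ±5, unit sd) a *single* adaptive-Metropolis chain also
ends up crossing between modes — covariance adaptation inflates the
proposal sd to ≈7, comparable to the mode separation of 10, once the
scale-tuning transient first reaches the far mode. Tempering is the
robust mechanism (its mode split is balanced from the start and does not
depend on a lucky transient), but at this separation and budget the
single-chain comparison does not show the textbook "stuck in one mode"
failure; that failure reappears at larger separations, in higher
dimensions, or with frozen adaptation.

Diagnostics: Geweke burn-in compares the means of the first 10% and last
50% of the retained chain via spectral-variance z-scores (initial
positive sequence of autocovariances), scanning discard fractions
0, 0.1, …, 0.5; zero-variance chains are flagged degenerate. Effective
sample size is n/(1 + 2 Σ ρ_k) with the same truncation rule, minimized
over parameters.

## Storage, engines, CLI

Results serialize to a versioned HDF5 layout (`/meta`, `/problem`,
`/optimize/run_<k>`, `/profile/<id>`, `/sample/<name>`), self-describing
and bit-exact on round trip including NaN/inf sentinels; options are
canonical JSON attributes (HDF5-native nested structures are
dialect-prone). Writes go to a temporary file with an atomic rename.
Chain subsampling (≤ 10⁴ rows) happens only in CSV report exports; stored
traces are complete.

`map_parallel` executes pure tasks serially, multi-threaded or
multi-process with per-task seeds `seed_root + index`; output order
matches input order and results are identical across backends, so
parallelism never leaks into results. A raising task yields a failure
record in its slot.

The CLI (`inferode simulate|optimize|profile|sample|report`) is a thin
layer over the library: exit 0 on success, 1 on validation/usage errors,
2 on runtime failures; seeds and options are logged to stderr. Plot
generation is intentionally absent — CSV/JSON exports are the tested
reporting surface.

## Known limitations

- No SBML import; models come from the built-in registry.
- Forward sensitivities only; adjoint methods (preferable for many
  parameters) are not implemented.
- No pre-equilibration, discrete events, or state-reinitializing
  conditions.
- Hierarchical solving assumes a shared σ per scaling group; general
  weighted couplings are not closed-form here.
- Single-seed chains only: no multi-chain R-hat diagnostics.
- The Gaussian noise model is fixed; no outlier-robust likelihoods.
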