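# Methods

## Model and assumptions

A cell grows deterministically and exponentially in size, ds/dt = μs, and
divides in one step with instantaneous rate h = k·s^λ (default λ = 1).
Division is exactly symmetric: the followed daughter is born at half the
mother's division size, with no partitioning noise and no cell-to-cell
growth-rate variability. Under mother-machine semantics (one descendant
kept per division) the population size is fixed, the lineages are
independent, and the size path of each lineage is a deterministic function
of its division count: s(t) = s₀e^{μt}/2^{n(t)}.

Everything therefore reduces to the counting process n(t), a time-
inhomogeneous pure birth process whose rate in state i is
k(s₀/2^i)^λ·e^{λμt}. For λ = 1 the added size per cycle is exponential with
mean Δ̄ = μ/k independent of birth size, i.e. the adder strategy with
E[s_d|s_b] = s_b + Δ̄ and CV²_Δ = 1. λ ≠ 1 tilts the strategy away from the
adder; the simulator and FSP solver support it, the analytic recursion
implements the λ = 1 kernel only.

Parameters (units): μ (1/time), k (1/(size^λ·time)), s₀ (size), λ
(dimensionless). Two derived scales organise everything: the doubling time
τ = ln2/μ and the dimensionless θ = k·s₀/μ. All defaults are the canonical
dimensionless point μ = k = ln2, s₀ = 1, so τ = 1, θ = 1, Δ̄ = 1. One
exponential prefactor appears with two symbols in the added-size density as
printed elsewhere; normalisation forces both to equal μ/k and the package
treats them as one quantity.

## Solution routes and numerical choices

**Closed form / recursion.** P₀(t) = exp[−θ(e^{μt}−1)] exactly. Each Pᵢ
follows from P_{i−1} by a cumulative integral against the kernel
exp[μt′ + (ks₀/μ2^i)e^{μt′}]. Substituting u = e^{μt′} turns the kernel
integral into (1/μ)∫e^{a_i u}P_{i−1}(u)du with a_i = θ/2^i, and every Pᵢ is
a finite sum of exponentials in u, so cumulative Simpson quadrature on a
uniform u-grid converges at fourth order. The grid (default 4097 nodes) is
doubled until two successive refinements agree to `quad_tol` (default
10⁻⁹, measured as max absolute difference on the requested times); failure
to converge raises with a diagnostic. The route overflows for
θ·e^{μt}/2 ≳ 700 and then raises, pointing to FSP.

**Finite state projection.** States 0..N with no inflow from beyond N; the
deficit leak(t) = 1 − ΣᵢPᵢ(t) is nonnegative, nondecreasing, and bounds the
truncation error of the whole distribution. The ODE system is integrated
with LSODA at rtol/atol = 10⁻⁹/10⁻¹² (defaults; probabilities near 10⁻⁶
must be resolved) using the analytic Jacobian. No reflecting boundary and
no renormalisation: leak is reported, never hidden; moments computed on the
truncated support carry a flag where leak exceeds 10× the rtol. Negative
round-off probabilities are kept raw internally (so conservation checks are
exact) and clamped to zero only for reporting. `fsp_auto_truncate` finds
the smallest N meeting a leak bound by doubling then bisection (hard cap
512). Because the propensity separates as A·e^{λμt} with constant A, the
substitution w = (e^{λμt}−1)/(λμ) makes the system autonomous and
P(t) = expm(A·w(t))·e₀ exact; `expm_propagate` implements this as an
independent cross-check of the integrator.

**Exact simulation.** The cumulative hazard over a cycle is analytic, so
interdivision times are drawn by inverse transform:
T = (1/λμ)·log(1 + λμE/(k·s_b^λ)) with E a unit exponential. No thinning,
no rejection, no time discretisation — the sampler is exact for any λ > 0,
and moments are grid-independent up to sampling error. Each cell receives
its own `SeedSequence`-spawned substream, so ensembles are reproducible and
order-independent. Ensemble summaries report normal-approximation 95%
half-widths for means and a variance-of-variance estimate for variances;
both are approximate, noticeably so at very early times when the count is
nearly degenerate.

**Size statistics.** At any grid time the size law is the Dirac mixture
with atoms s₀e^{μt}/2^i weighted by Pᵢ(t); moments follow by direct
summation and agree with the atom sets to round-off by construction. Sizes
are reported absolutely and as s/s₀ (the relative form is the natural
plotting axis). Atoms lighter than 10⁻¹² are dropped from written files
only. The envelope over several initial sizes is the tagged union of atom
sets weighted equally across sources (so total mass stays 1); it is kept as
discrete atoms — any smoothing is a visualisation choice, not part of the
data model. An initial-size distribution is discretised into
equal-probability quantile nodes (midpoint quantiles; deterministic, so
tests are exact) and atoms coinciding to relative tolerance 10⁻⁹ are
merged; the discretisation converges weakly as nodes are added, with the
stochastic cross-check supplied by simulating sampled initial sizes.

**Grids.** The default output grid places 73 points per doubling time
(512 points on [0, 7τ]), chosen so the step divides τ exactly — required to
evaluate the asymptotic translation invariance ‖Pᵢ(t) − P_{i−1}(t−τ)‖ → 0
without interpolation.

## What the generated data emulate — and what they do not

The simulator *is* the study system: the model has no external data, and
ensembles generated at the canonical parameter point (10⁴ cells, horizons
of 7–14τ) define the conditions under which the analytic and FSP routes are
validated. Real mother-machine data additionally show partitioning noise,
growth-rate variability between cells and over time, measurement error,
and an added-size CV² an order of magnitude below this model's value of 1
(a single rate-limiting division step is the noisiest case; multi-step
triggering would reduce it). Passing tests therefore demonstrate internal
correctness of the three routes and the adder property of the rate law, not
quantitative agreement with any particular organism.

One estimator subtlety: pooling all cycles *completed* by a fixed horizon
is length-biased (in-progress long cycles are excluded), shifting the mean
added size down by ~7% at a 10τ horizon. Cycle pools used for added-size
statistics therefore take the first 10 generations of each lineage with a
14τ horizon; interdivision times have double-exponential tails, so these
generations complete with overwhelming probability and the pool is
unbiased.

## Problem sizes and determinism

Deterministic checks use FSP truncations N ≤ 30 and grids of ≤ 1024 points
and complete in seconds. Stochastic checks use 10⁴ cells for moment
concordance (95% bands at ≥ 90% of 512 grid times) and 5×10⁴ pooled cycles
for the added-size CV² and the adder regression, placing the stated
tolerances at or beyond two Monte-Carlo standard errors. All stochastic
tests are seeded; identical seed and configuration reproduce outputs
bit-identically.

## Known limitations

- Fixed-population (mother-machine) ensembles only; population trees that
  keep both daughters are out of scope.
- No partitioning errors, asymmetric division, or growth-rate noise.
- The division-count variance plateau (~0.75 at θ = 1) is a numerical
  observation; no closed form is implemented.
- The envelope over initial sizes is the locus of delta atoms; no analytic
  envelope curve is provided.
- The quadrature recursion is limited to λ = 1 and to ranges where
  exp(θ·e^{μt}/2) is representable in double precision.
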