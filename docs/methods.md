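# Methods

## Model and decision rule

The package implements a single-arm, binary-endpoint basket design with
*I* strata. Responses are binomial, `r_i ~ Bin(n_i, p_i)`, with conjugate
beta priors (uniform by default). Borrowing multiplies each pair of strata's
posterior shape parameters into one another through similarity weights
`w_ij = 1(w~_ij^eps > tau) * w~_ij^eps`, where `w~_ij = 1 - D(post_i, post_j)`
and `D` is the Jensen-Shannon divergence of the *stand-alone* posteriors
under the natural logarithm (so `w~` ranges over `[1 - log 2, 1]`), or
optionally the Hellinger distance, which has the closed form
`1 - B((a1+a2)/2, (b1+b2)/2) / sqrt(B(a1,b1) B(a2,b2))` and needs no
quadrature. Stratum *i* is detected when its borrowing posterior puts mass at
least `lambda` above the target rate `p*_i`.

Conventions where the defining equations leave room:

* **Self-weight.** `w_ii` is forced to 1. Under a literal reading, the grid
  value `tau = 1` would zero the diagonal and produce a `Beta(0, 0)`
  borrowing posterior; a stratum must always retain its own data for the
  design to be well defined.
* **Strictness.** The weight cutoff is strict (`w~^eps > tau`) and the
  detection rule inclusive (`>= lambda`), exactly as written in the design's
  definition.
* **Weight normalization.** A variant that divides the weights by the
  maximal unequal-pair similarity appears only inside the argument about the
  redundancy of `eps` and `tau`; the primary, unnormalized definition is what
  the package implements throughout.
* **Numerics of the decision.** The posterior tail condition
  `P(p > p*) >= lambda` is evaluated on the *lower* regularized incomplete
  beta function as `I_{p*}(a, b) <= 1 - lambda`. The two forms are
  algebraically identical, but the upper tail rounds to 1.0 in double
  precision for strongly positive data, which would make `lambda = 1`
  spuriously detect; the lower-tail form keeps the boundary cases exact.
* **Extreme borrowing boundary.** For `tau` strictly inside (0, 1),
  `eps_extreme(tau) = log(tau) / log(w~*)`, with `w~*` the maximum raw
  similarity over all pairs of per-stratum outcomes with unequal response
  counts, enumerated over the layout's sample sizes. Above the boundary the
  weight matrix equals the equal-responses indicator, so further increases of
  `eps` or `tau` cannot change any decision. For equal sample sizes the
  pairwise construction is the same for every stratum pair, so the boundary
  does not depend on the stratum count; the implementation nevertheless
  enumerates all pairs so unequal layouts are handled.

## Divergence computation and caching

The Kullback-Leibler integrals behind the Jensen-Shannon divergence are
evaluated with adaptive quadrature (`scipy.integrate.quad`, absolute
tolerance 1e-11), with the integrand defined as 0 wherever the numerator
density vanishes. With uniform priors all posterior shapes are at least 1, so
densities are bounded and there are no endpoint singularities in the studied
configurations. Quadrature noise is clipped at the theoretical bounds
`[0, log 2]`.

Raw similarity depends only on the two posterior shape pairs, so values are
memoized process-wide and assembled into per-sample-size lookup tables. Exact
enumeration over all response vectors therefore costs `prod(n_i + 1)`
decisions but only `O(max_i (n_i + 1)^2)` integrals for equal sample sizes.

## Operating characteristics

Operating characteristics are frequentist expectations of the Bayesian
decision rule under true binomial sampling. The exact engine enumerates every
response vector, weights it by its product-binomial probability (the total
mass is asserted to be 1 within 1e-12) and accumulates marginal rejection
rates, `EWP = P(some active stratum detected)`, `FWER = P(some inactive
stratum detected)` and the expected number of correct decisions. For the
global null the EWP is defined as 0, and for the global alternative the FWER
is 0 — the measure of an empty union. Enumeration refuses above a
configurable limit of 3·10^6 response vectors, directing the caller to the
Monte-Carlo engine (1000 simulated trials by default, standard errors
`sqrt(r(1-r)/n_mc)` attached, reproducible under a seed with per-call streams
derived as seed + call index).

Two performance devices matter for optimization loops and are exact, not
approximations:

* one decision sweep per tuning vector is shared by every scenario of a set
  (scenarios only reweight the enumerated outcomes);
* for exchangeable strata (equal sizes, priors and targets — all studied
  layouts) the decision for stratum *i* depends only on `(r_i, multiset of
  the other responses)`, so posterior tails are evaluated once per unique
  combination, about a twentyfold reduction at four strata of 20 patients.

## Scenario sets

Seven pre-specified sets span 3 to 20 strata, inactive rates 0.01-0.20,
active rates 0.10-0.50 and total sample sizes 72 to 480. Stepped scenarios
place inactive strata first; the four-stratum n=20 set carries two additional
mixed-rate scenarios, and the twenty-stratum set steps the number of active
strata by two. The target rate `p*_i` is set to the set's inactive rate `p0`
for every stratum, the convention of the underlying design; a stratum is
active exactly when its true rate exceeds the target, which makes all four
strata of the mixed scenario (0.4, 0.4, 0.3, 0.5) active against `p* = 0.15`.
Scenario ordering is ascending in the number of active strata with mixed
scenarios last.

## Utility functions

Twelve utilities are studied, all maximized: the discontinuous family-wise
power-error function (EWP if the reference-scenario FWER stays strictly below
`eta1 = 0.05`, else `-xi1 * FWER`), the analogously gated expected number of
correct decisions, the two-level family-wise power-error function
(`EWP - xi1*FWER - xi2*(FWER - eta2)^+` with `eta2 = 0.1`), its stratum-wise
analogue, and the scenario-averaged versions of all four, plain and with a
hard penalty `-xi3 * max TOER` (with `xi3 = 1000`, `eta3 = 0.2`) on the
maximal type-I error over all scenarios and inactive strata. The hinge
indicator is active only strictly above zero, so an FWER exactly at `eta2`
incurs no second-level penalty. Scenario weights default to uniform and must
sum to 1; `u_averaged` is linear in them. For single-scenario utilities the
reference scenario is the set's global null, and the default scenario of
interest has about half the strata active (2 of 3, 2 of 4, 4 of 8). The
`xi3 * eta3 > |min u|` sanity condition is checkable from emitted tables but
not enforced, since the minimum averaged utility is unknown a priori.

Utility evaluation uses the exact backend whenever the layout is below the
enumeration limit and the seeded Monte-Carlo backend otherwise, mirroring the
exact/simulation split of the study protocol.

## Optimizers

All eight study configurations maximize over the box `lambda, tau in [0, 1]`,
`eps in [0, 25]`. The upper bound 25 is the grid's restriction of the
conceptually unbounded shape-exponent axis; for the studied layouts it
already lies beyond the extreme borrowing boundary at the relevant `tau`
values, so nothing of design relevance is cut off, and it makes the
bounded-annealing hypercube finite and comparable across algorithms. Every
objective call passes through one counting wrapper, so budgets (default 1000
evaluations) are enforced uniformly, and out-of-bounds proposals of the
unbounded annealing variant consume budget while being treated as invalid
(value `-inf`, never accepted). All stochastic algorithms are bit-reproducible
given a seed.

* **Simulated annealing** (bounded at start temperatures 100/10/1 with
  reflection at the walls; unbounded at 10): geometric cooling to a final
  temperature of 1e-8 over the budget, one evaluation per temperature step,
  Metropolis acceptance. Proposals are independent Gaussian steps whose
  width decays geometrically from 10% of each axis range to 5% of that
  initial width. The defining description fixes the start temperatures and
  one evaluation per step but no schedule; this one was chosen so the walk
  both escapes local structure early and localizes late — the final thermal
  jitter radius (~sqrt(T)) stays far below the proposal width, which is what
  lets 1000-evaluation runs settle onto an optimum instead of rattling
  around it. An out-of-bounds start point is rejected for the unbounded
  variant.
* **Differential evolution**: canonical rand/1/bin with population 40,
  scale factor 0.8, crossover rate 0.5, one guaranteed donor component,
  greedy (>=) selection, clipping at the bounds; a partially completed final
  generation is truncated at the budget.
* **Grey wolf optimizer**: the original linear-decay variant, population 40;
  candidates move to the mean of three leader-guided points with the
  exploration coefficient decaying linearly from 2 to 0 over the generation
  budget, clipped at the bounds.
* **COBYLA**: adapter over `scipy.optimize.minimize(method="COBYLA")` with
  parameter-space tolerance 1e-6 and no value-space stopping; box bounds are
  posed as linear constraints and the wrapper additionally folds iterates
  into the box before evaluation, so every recorded evaluation is feasible.
  Non-convergence is reported in the result, never raised.
* **Grid search**: the fixed 10×10×10 grid (1000 points) over
  `lambda in {0.2, ..., 0.9, 0.99, 0.999}`, `eps in {0, 0.5, 1, 1.5, 2, 5,
  10, 15, 20, 25}`, `tau in {0, 0.1, ..., 0.8, 1.0}`, visited in row-major
  (lambda, eps, tau) order with ties broken by first occurrence.

## Study runner

Part I runs the eight configurations on two test problems (scenario-averaged
two-level family-wise power-error and scenario-averaged expected correct
decisions on one scenario set), stochastic algorithms `n_runs` times with
seeds `seed + run index` (protocol defaults: 50 runs, first seed 1856, start
vector (0.2, 0.5, 0)), COBYLA and grid search once. Internal consistency is
summarized by means, standard deviations, normal 95% confidence intervals and
ranges of the optimal values and tuning-vector components, with the standard
error of each sample standard deviation from the gamma-function formula
`s * G((n-1)/2)/G(n/2) * sqrt((n-1)/2 - (G(n/2)/G((n-1)/2))^2)` (coefficient
0.10127 at n = 50, asymptotically `1/sqrt(2(n-1))`), evaluated in log space.
**Internal reliability** — named but not defined by the selection rule — is
implemented as the fraction of runs whose best value lies within 1e-4 of the
per-problem best. **External reliability** is the rate of matching the
grid-search reference within 1e-9 (absorbing floating-point noise). Selection
keeps algorithms with mean internal reliability above 0.99, then mean success
rate above 0.99, and picks the fastest survivor by mean wall time. Timing and
memory are reported, never asserted: they are hardware facts, not design
properties.

Part II optimizes all twelve utilities per scenario set with the selected
algorithm (seed 899), then tabulates every scenario's marginal rejection
rates, FWER, EWP, ECD and all twelve utilities' values at each found optimum;
Part III produces the same tables at the fixed vectors (0.99, 2, 0) and
(0.99, 2, 0.5). The further analyses (a) compare matched exact operating
characteristics and timings under Jensen-Shannon vs Hellinger similarity and
report the Spearman rank correlation of the two similarity tables, and
(b) tabulate, for two baskets with target 0.2, the inactive basket's type-I
error as the partner's true rate sweeps 0.2 to 1.0 in steps of 0.05 for a
configurable list of `(eps, tau)` combinations. The defining description of
this two-basket analysis fixes everything except the per-stratum sample size;
the package uses 24 patients per basket, the flagship three-basket set's
size, so the curves are directly comparable to that set's operating
characteristics.

## Problem sizes and what the shipped defaults show

The full protocol scale (four-stratum n=20 exact backend, budget 1000, 50
runs per stochastic algorithm) is reachable through `StudyConfig()` but takes
cluster-scale time; the shipped desk profile (`StudyConfig.desk_profile()`:
three strata of five patients, budget 200, 10 runs, flagship set only)
exercises every code path and measure in minutes on one CPU. Results from the
desk profile demonstrate the machinery — selection filters, measure tables,
reproducibility — not the protocol-scale scientific conclusions: with a
budget of 200 the grid reference is truncated to its first 200 points and
stochastic optima are noisier than at full budget.

The scenario machinery generates product-binomial data under fixed true
rates. Real basket trials add features the generator deliberately omits —
staggered accrual, interim looks, non-exchangeable strata, prior-data
conflict — so passing tests certify the computations of this design under
its stated sampling model, not trial performance beyond it.

## Known limitations

Binary endpoints only; one analysis stage; equal priors across strata in the
provided scenario sets (the engines accept unequal priors and sample sizes,
with a slower decision path). MCSEs are the plain binomial/plug-in forms, no
jackknife or bias correction. The normalized-weight variant of the borrowing
rule and patient-level cost/gain utilities are out of scope.
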