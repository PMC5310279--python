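# Methods

This note records the statistical procedures the package implements, the
conventions chosen where the literature admits several, and what the
synthetic-data studies do and do not demonstrate.

## Cox partial likelihood machinery

All strategies rest on the Breslow form of the log partial likelihood:
tied event times share one risk set R_k = {j : t_j ≥ t_k} and contribute
separate event terms. The Efron tie correction is deliberately out of
scope: the penalized solver uses the Breslow form, and using the same
convention for the unpenalized refits keeps selection and reporting
consistent. Before any exponentiation the linear predictor is shifted by
its maximum, so risk-set sums cannot overflow regardless of covariate
scale.

Unpenalized fits use Newton–Raphson from β = 0 with step-halving (at most
40 halvings per step, 100 iterations). Convergence is declared when the
gradient's maximum absolute entry falls below 1e−8 or the relative
log-likelihood change falls below 1e−10; a flattening likelihood whose
coefficients run away (|β| > 100) is flagged *non-converged*, the signature
of monotone likelihood under separation. Standard errors are the square
roots of the diagonal of the inverse observed information at β̂; a singular
information matrix raises an error naming the collinear columns (found by
pivoted QR). The Hessian is assembled without materializing per-risk-set
outer products, using Σ_k S₂(k)/S₀(k) = Xᵀ diag(w·A) X with
A_j = Σ_{k: j∈R_k} 1/S₀(k), which keeps refits with hundreds of features
cheap.

Harrell's concordance treats a pair as permissible iff the strictly
earlier time is an event (tied times are never permissible), counts score
ties as half-concordant, and is computed by vectorized exhaustive pairing —
n here is at most a few hundred, so the O(n²) form is both the oracle and
the implementation. The goodness-of-fit statistic is the Cox–Snell
generalized R² = 1 − exp(−(2/n)(ℓ(β̂) − ℓ(0))), the quantity printed by
standard Cox software summaries; other pseudo-R² variants (e.g.
Nagelkerke-normalized) are not reported.

## Penalized solver

The L1-penalized problem is solved on standardized covariates (mean 0,
population-variance 1; coefficients are reported back on the original
scale) over a log-spaced grid of 100 penalties from λ_max — the analytic
boundary max_j |g_j(0)|/n below which the first coefficient activates —
down to λ_max·0.01 when p > n (1e−4 otherwise). Each grid point
warm-starts the next. The algorithm is penalized IRLS: the likelihood is
replaced by its weighted least-squares approximation at the current linear
predictor (diagonal Hessian weights w·A − w²·B, the standard construction
for the Cox deviance), and the penalized WLS subproblem is solved
*exactly* by an active-set method — solve the quadratic restricted to the
current sign pattern, clip the first coefficient that crosses zero, admit
the worst violator among the zeros until none remains. Because the
diagonal approximation alone converges slowly on strongly correlated
designs deep in the path, a full-Hessian Newton polish on the
sign-restricted active set finishes each grid point; the exact-gradient
KKT conditions (|g_j|/n ≤ λ for zero coefficients, g_j/n = λ·sign(β_j)
for active ones, tolerance 1e−5 with typical residuals below 1e−9) are
checked at every grid point and are the solver's acceptance criterion.
Tests additionally cross-check whole paths against the glmnet-family
solver in scikit-survival.

Cross-validation uses the Verweij–van Houwelingen partial-likelihood
deviance: fold k contributes −2[ℓ_full(β̂₋ₖ) − ℓ₋ₖ(β̂₋ₖ)], which avoids
evaluating a partial likelihood on tiny test folds. Folds are assigned by
a seeded permutation stratified on the event indicator (10 folds by
default), and the selected penalty is the deviance minimizer ("lambda.min");
the 1-SE rule is available but not default, since the operating point of
interest is a selection of roughly ten to twenty features, which the
minimizer produces.

## Screening

The marginal screen fits all p one-covariate Cox models simultaneously
with a damped vectorized Newton iteration (steps clipped at ±2) and keeps
the d = ⌊n/log n⌋ largest |β̂_m| by default, ties broken by feature order;
non-converging marginal fits get statistic 0 and are logged, never fatal.
The conditional screen refits C₀ ∪ {m} *jointly* for every candidate m —
the conditioning coefficients are re-estimated per candidate, not frozen —
and retains candidates whose Wald p-value is below γ; the default
threshold is the γ = 1/p rule, with p the total number of covariates.
A magnitude rule (|β̂_m| ≥ γ) is provided as an alternative mode, but the
p-value rule is the operating default: a fixed cut on |β̂_m| is not
scale-invariant, while the Z-test calibrates each candidate against its own
standard error. Candidates whose conditional fit is singular (e.g. a
duplicate of a C₀ member) or non-convergent are excluded and logged.

In CoxSisLasso, an empty Lasso prior set falls back to the marginal top-d
set as the conditioning set, with a prominent warning. When no candidate
passes the conditional screen, the final penalized fit over C₀ ∪ C₁ = C₀
would merely re-run the Lasso on variables the Lasso already chose, so the
implementation short-circuits: the final selection is C₀ itself, making
the degenerate case exactly coincide with CoxLasso's selection.

## Evaluation

Time-dependent ROC uses the cumulative-case / dynamic-control definition:
at horizon t, cases have an observed event by t and controls are still
event-free (observed time > t). δ(t) is read as "event at or before t".
Two estimators are provided. `naive` drops subjects censored before t.
`km_cd` weights each case by the inverse Kaplan–Meier estimate Ĝ(T_i⁻) of
the censoring survival function (controls carry a common weight that
cancels); with zero censoring the two coincide exactly, which is the
tested bridge to the brute-force pairwise oracle. Cutoffs sweep the unique
scores plus ±∞ so the curve runs from (0,0) to (1,1), and the AUC is the
trapezoidal area. Subjects censored exactly at t are neither cases nor
controls. The CLI's default evaluation horizon is 30, in whatever unit the
input times carry (months, for typical clinical follow-up tables).

Train/test splitting is a seeded uniform draw without replacement,
redrawn (at most 20 times) until both halves retain at least two events;
the test set is always the complement of the training draw.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k), evaluated
as a sum of pmf terms computed in log-gamma form (with a cached
log-factorial table); out-of-support k yields pmf 0 so tail sums need no
bounds logic. The default universe is the feature space the selection was
made from (post-filter), configurable; genes outside the universe are
dropped with a warning. Benjamini–Hochberg adjustment (via statsmodels) is
applied across the tested sets by default, Bonferroni optionally — the
enrichment sources this package emulates report unadjusted hypergeometric
p-values, so the adjustment choice is surfaced explicitly.

Input filtering follows the microarray convention of discarding
near-constant features by interquartile range, with the linearly
interpolated quantile definition (numpy's default, R's type 7) fixed so
results are deterministic; the default keeps the top 20% of features by
IQR, and an absolute-IQR cutoff is available.

## Synthetic data

The generator draws covariates from a zero-mean unit-variance Gaussian
with independent, AR(1) or equicorrelated structure and inverts the
cumulative baseline hazard: T = −log U/(rate·e^η) for the exponential
baseline, T = scale·(−log U/e^η)^{1/shape} for Weibull. Censoring times
are uniform on (0, c*) with c* calibrated by bisection so the expected
censoring fraction matches a target (realized rates land within ±0.05 for
n ≥ 200); censoring is independent of the covariates, matching the random
censoring assumption of the model. The hidden design places
β = (b, b, b, −3ρb) on four equicorrelated covariates so the fourth is
exactly uncorrelated with the linear predictor. The nulling is exact at
the covariance level only — the marginal Cox slope is not a pure
covariance — so the marginal coefficient of the hidden covariate is only
approximately zero, and the simulation acceptance thresholds are rates
over replicates rather than exact statements.

What the generator does *not* emulate: microarray noise (probe effects,
background, batch structure across collection sites), heavy-tailed or
skewed expression distributions, and informative censoring. Passing the
simulation studies therefore demonstrates the selection logic under the
model's own assumptions, not robustness to real-array artifacts;
normalization and probe-level preprocessing are upstream of this package.

## Study sizes and numerical choices

The two simulation studies run 50 seeded replicates each at n = 300,
p = 500: the strong-signal study (five AR(1)-correlated effects of
|β| = 1, 25% censoring) checks that all three strategies recover the full
support in at least 45/50 replicates; the hidden study (ρ = 0.5, b = 1,
25% censoring) checks that CoxSis omits the hidden covariate in ≥ 40/50
replicates while CoxSisLasso includes it in ≥ 40/50, wins on support
sensitivity per seed, and attains at least the same out-of-sample mean
AUC(t) in a majority of replicates (scored on an independent 150-sample
draw from the same population, over the 20–80% quantiles of the test
event times). These batches use a compute-light cross-validation
configuration — 5 folds, a 50-point grid down to 0.05·λ_max — chosen so a
replicate's selection sits well inside the grid; the packaged defaults
(10 folds, 100 points, ratio 0.01) are used everywhere a single analysis
is run. All randomness is driven by explicit integer seeds
(`numpy.random.default_rng`); there is no global RNG state and no
wall-clock input, so every pipeline output is byte-reproducible.

## Known limitations

- Breslow ties only; data with massive tie groups (coarsely discretized
  times) would favor the Efron correction the package does not implement.
- The conditional screen refits one model per candidate; at p in the tens
  of thousands this is an O(p) sweep of small Newton fits — robust, but
  minutes rather than seconds.
- The penalized path deep below the cross-validated optimum (active sets
  approaching the event count) is ill-conditioned by nature; solutions
  there satisfy the KKT tolerance but inherit wide sampling variability.
- No baseline-hazard estimate is produced: selections, refit coefficients
  and rank-based accuracy measures never require h₀(t).
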