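# coxsislasso

Variable selection for high-dimensional censored survival data, built for
gene-expression studies where the number of features *p* far exceeds the
number of samples *n* (the P ≫ N regime in which the ordinary Cox maximum
partial-likelihood estimate does not exist). The package implements and
compares three selection strategies, together with the evaluation and
enrichment machinery needed to interpret their output:

- **CoxLasso** — L1-penalized Cox regression over all features, with the
  penalty chosen by cross-validated partial-likelihood deviance;
- **CoxSis** — marginal sure independence screening (one-covariate Cox fit
  per feature, keep the top *d* by |β̂|) followed by the penalized fit on
  the survivors;
- **CoxSisLasso** — a Lasso-conditioned screen: the penalized selection
  C₀ becomes a conditioning set, every remaining feature *m* is refit
  jointly with C₀ and retained in C₁ when the Wald p-value of β̂ₘ falls
  below γ = 1/p, and a final penalized fit on C₀ ∪ C₁ picks the selection.

The point of the third strategy is the failure mode of the second: a
covariate can be jointly predictive of survival yet *marginally* invisible
(its covariance with the linear predictor cancels against its correlated
partners), so marginal screening discards it. Screening conditional on a
prior set recovers it.

## The model

The Cox proportional-hazards model writes the hazard of subject *i* as
h_i(t) = h₀(t) exp(x_iᵀβ). With D the event indices and R_k the risk set
at the k-th event time, β̂ maximizes the log partial likelihood

    ℓ(β) = Σ_{k∈D} [ x_kᵀβ − log Σ_{j∈R_k} exp(x_jᵀβ) ]

(Breslow convention for tied event times). The penalized problem solved by
every strategy's selection step is

    min_β  −(1/n) ℓ(β) + λ Σ_j |β_j| ,

whose solutions are verified against their Karush–Kuhn–Tucker conditions at
every grid point. Reported models are always an **unpenalized refit** on
the selected features, summarized by coef, exp(coef), se(coef), Wald z and
p-value, the Cox–Snell generalized R² = 1 − exp(−(2/n)(ℓ(β̂) − ℓ(0))) and
Harrell's concordance index. Predictive accuracy over time uses the
cumulative/dynamic time-dependent ROC: at horizon *t*, cases are subjects
with an event by *t*, controls are subjects event-free at *t*, and
sensitivity(c, t) = Pr{xᵀβ > c | case} is swept against
1 − specificity(c, t), with a Kaplan–Meier correction for censoring.
Selected gene lists are tested for pathway over-representation with the
hypergeometric upper tail P(X ≥ k) given a universe of N genes, K pathway
members and n selected genes.

A fully seeded synthetic-data module generates expression + survival data
from a known sparse Cox model (configurable correlation structure, baseline
hazard and calibrated censoring rate), including the equicorrelated
"hidden covariate" design with β = (b, b, b, −3ρb), for which
Cov(X₄, Xᵀβ) = 0 exactly.

## Worked example

```python
import coxsislasso as cl

sim = cl.simulate_dataset(cl.hidden_variable_config(
    n=300, p=500, rho=0.5, beta0=1.0, seed=2, censoring=0.25))
ds = sim.dataset
cfg = cl.StrategyConfig(n_folds=5, seed=0, n_lambda=50, lambda_min_ratio=0.05)
for res in (cl.run_coxsis(ds, cfg), cl.run_coxsislasso(ds, cfg)):
    print(res.strategy, len(res.selected_ids), "genes,",
          "includes hidden" if ds.feature_ids[3] in res.selected_ids
          else "misses hidden",
          f"R^2={res.r2:.3f} concordance={res.concordance:.3f}")
```

prints

```
CoxSis 3 genes, misses hidden R^2=0.440 concordance=0.746
CoxSisLasso 19 genes, includes hidden R^2=0.741 concordance=0.853
```

G00004 is the truly active covariate with β₄ = −1.5 whose marginal Cox
coefficient is ≈ 0.06 (it ranks last of 500 in the marginal screen), so
CoxSis cannot keep it; conditioning on the Lasso prior set exposes it, and
the richer CoxSisLasso model fits and discriminates visibly better. The
scripts in `examples/` walk through each capability (selection reports,
out-of-sample AUC(t) comparison, the hidden-covariate construction, and
pathway enrichment) with commentary on the printed numbers.

A `coxsislasso` command-line interface wraps the same pipeline
(`simulate`, `filter`, `select`, `evaluate`, `enrich`, `compare`); every
threshold actually used (λ, γ, d, fold seed, dropped samples) is written to
a run log, and identical invocations are byte-identical.

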