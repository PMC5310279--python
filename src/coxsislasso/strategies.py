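"""The three end-to-end variable-selection strategies and their comparison.

* CoxLasso  — L1-penalized Cox with cross-validated lambda on all features.
* CoxSis    — marginal screening to the top-d features, then CoxLasso on them.
* CoxSisLasso — CoxLasso gives a prior set C0; conditional screening with
  threshold gamma (default 1/p) augments it with C1; a final penalized fit on
  C0 union C1 picks the selection.

Each strategy ends with an UNPENALIZED Cox refit on its selection, from which
the reported Wald table, generalized R^2 and concordance derive — the
penalized coefficients themselves are used only to select.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cox, evaluation, lasso, screening
from .data import SurvivalDataset

__all__ = ["StrategyConfig", "StrategyResult", "ComparisonReport",
           "run_coxlasso", "run_coxsis", "run_coxsislasso",
           "compare_strategies", "overlap_summary"]


@dataclass
class StrategyConfig:
    """Shared knobs for the three strategies (seeds are explicit, never clock)."""

    n_folds: int = 10
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    rule: str = "min"            # CV lambda rule: "min" or "1se"
    d: int | None = None         # screening budget; default floor(n / log n)
    gamma: float | None = None   # conditional threshold; default 1/p
    t_grid: tuple | None = None  # AUC evaluation times for comparisons
    estimator: str = "km_cd"

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


@dataclass
class StrategyResult:
    strategy: str
    selected_indices: np.ndarray
    selected_ids: list
    refit: cox.CoxFit
    wald: cox.WaldReport | None
    r2: float
    concordance: float
    provenance: dict             # feature id -> lasso_prior | screened | augmented
    config_snapshot: dict
    warnings: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.selected_indices) == 0

    def risk_scores(self, ds: SurvivalDataset) -> np.ndarray:
        """x' beta_hat from the unpenalized refit, on any aligned dataset."""
        if self.empty:
            return np.zeros(ds.n)
        pos = {f: i for i, f in enumerate(ds.feature_ids)}
        idx = [pos[f] for f in self.selected_ids]
        return ds.X[:, idx] @ self.refit.beta

    def to_dict(self) -> dict:
        d = {
            "strategy": self.strategy,
            "selected_ids": list(self.selected_ids),
            "coef": self.refit.beta.tolist(),
            "se": self.refit.se.tolist(),
            "r2": self.r2,
            "concordance": self.concordance,
            "provenance": dict(self.provenance),
            "config": dict(self.config_snapshot),
            "warnings": list(self.warnings),
        }
        if self.wald is not None:
            d["z"] = self.wald.z.tolist()
            d["p_value"] = self.wald.p_value.tolist()
            d["hazard_ratio"] = self.wald.hazard_ratio.tolist()
        return d


def _finalize(ds: SurvivalDataset, strategy: str, selected: np.ndarray,
              provenance: dict, cfg: StrategyConfig,
              warn: list) -> StrategyResult:
    selected = np.asarray(sorted(int(i) for i in selected), dtype=np.int64)
    snapshot = {"strategy": strategy, **cfg.to_dict()}
    if selected.size == 0:
        refit = cox.fit_cox(ds, [])
        return StrategyResult(strategy, selected, [], refit, None,
                              0.0, 0.5, {}, snapshot,
                              warn + ["empty selection: null-model metrics"])
    refit = cox.fit_cox(ds, selected)
    wald = cox.wald_report(refit)
    scores = ds.X[:, selected] @ refit.beta
    return StrategyResult(
        strategy=strategy,
        selected_indices=selected,
        selected_ids=[ds.feature_ids[i] for i in selected],
        refit=refit,
        wald=wald,
        r2=cox.generalized_r2(refit),
        concordance=cox.concordance(scores, ds.time, ds.event),
        provenance={ds.feature_ids[i]: provenance.get(int(i), "screened")
                    for i in selected},
        config_snapshot=snapshot,
        warnings=warn,
    )


def run_coxlasso(ds: SurvivalDataset,
                 config: StrategyConfig | None = None) -> StrategyResult:
    """Penalized selection on all features, then unpenalized refit."""
    cfg = config or StrategyConfig()
    sel = lasso.lasso_select(ds, n_folds=cfg.n_folds, seed=cfg.seed,
                             n_lambda=cfg.n_lambda,
                             lambda_min_ratio=cfg.lambda_min_ratio,
                             rule=cfg.rule)
    prov = {int(i): "lasso_prior" for i in sel}
    return _finalize(ds, "CoxLasso", sel, prov, cfg, [])


def run_coxsis(ds: SurvivalDataset,
               config: StrategyConfig | None = None) -> StrategyResult:
    """Marginal screen to the top d, penalized selection within the survivors."""
    cfg = config or StrategyConfig()
    d = cfg.d if cfg.d is not None else screening.default_d(ds.n)
    screen = screening.marginal_screen(ds, d)
    ds_theta = ds.subset_features(screen.selected_indices)
    sel_local = lasso.lasso_select(ds_theta, n_folds=cfg.n_folds,
                                   seed=cfg.seed, n_lambda=cfg.n_lambda,
                                   lambda_min_ratio=cfg.lambda_min_ratio,
                                   rule=cfg.rule)
    sel = screen.selected_indices[sel_local]
    prov = {int(i): "screened" for i in sel}
    return _finalize(ds, "CoxSis", sel, prov, cfg, list(screen.log))


def run_coxsislasso(ds: SurvivalDataset,
                    config: StrategyConfig | None = None,
                    c0: np.ndarray | None = None) -> StrategyResult:
    """Lasso prior set C0, conditional augmentation C1, final penalized pick.

    ``c0`` may supply a precomputed prior selection (e.g. the CoxLasso
    selection under the same config) to avoid refitting the identical
    cross-validated path; when omitted it is computed here.
    """
    cfg = config or StrategyConfig()
    warn: list = []
    if c0 is None:
        c0 = lasso.lasso_select(ds, n_folds=cfg.n_folds, seed=cfg.seed,
                                n_lambda=cfg.n_lambda,
                                lambda_min_ratio=cfg.lambda_min_ratio,
                                rule=cfg.rule)
    else:
        c0 = np.asarray(c0, dtype=np.int64)
    if c0.size == 0:
        warn.append("empty Lasso prior set C0; falling back to the marginal "
                    "screen as the conditioning set")
        warnings.warn(warn[-1], stacklevel=2)
        c0 = screening.marginal_screen(
            ds, screening.default_d(ds.n)).selected_indices
    gamma = cfg.gamma if cfg.gamma is not None else screening.gamma_rule(ds.p)
    screen = screening.conditional_screen(ds, c0, gamma)
    c1 = screen.selected_indices
    prov = {int(i): "lasso_prior" for i in c0}
    prov.update({int(i): "augmented" for i in c1})
    if c1.size == 0:
        # degenerate augmentation: the candidate pool is exactly the set the
        # penalized fit already chose, so the final selection is C0 itself
        warn.append("no candidate passed the conditional screen; final "
                    "selection equals the Lasso prior set C0")
        return _finalize(ds, "CoxSisLasso", c0, prov, cfg,
                         warn + list(screen.log))
    pool = np.union1d(c0, c1)
    ds_pool = ds.subset_features(pool)
    sel_local = lasso.lasso_select(ds_pool, n_folds=cfg.n_folds,
                                   seed=cfg.seed, n_lambda=cfg.n_lambda,
                                   lambda_min_ratio=cfg.lambda_min_ratio,
                                   rule=cfg.rule)
    sel = pool[sel_local]
    return _finalize(ds, "CoxSisLasso", sel, prov, cfg,
                     warn + list(screen.log))


@dataclass
class ComparisonReport:
    """Train/test comparison of the three strategies under one seed."""

    results: dict                # strategy -> StrategyResult (train fits)
    test_concordance: dict       # strategy -> float
    t_grid: np.ndarray
    test_auc: dict               # strategy -> np.ndarray over t_grid
    overlap: dict                # 3-way selection overlap region counts

    def to_dict(self) -> dict:
        return {
            "strategies": {k: v.to_dict() for k, v in self.results.items()},
            "test_concordance": dict(self.test_concordance),
            "t_grid": self.t_grid.tolist(),
            "test_auc": {k: [None if np.isnan(a) else float(a) for a in v]
                         for k, v in self.test_auc.items()},
            "overlap": dict(self.overlap),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def overlap_summary(selections: dict) -> dict:
    """Counts of features per 3-way intersection region (Venn analogue)."""
    names = list(selections)
    sets = {k: set(v) for k, v in selections.items()}
    out = {}
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [nm for nm in names if nm not in inside]
        region = set.intersection(*[sets[nm] for nm in inside])
        for nm in outside:
            region -= sets[nm]
        out["&".join(inside)] = len(region)
    return out


def compare_strategies(ds_train: SurvivalDataset, ds_test: SurvivalDataset,
                       config: StrategyConfig | None = None) -> ComparisonReport:
    """Run all three strategies on train; score discrimination on test.

    The same CV seed is reused across strategies so differences are
    attributable to the selection logic rather than fold noise.
    """
    cfg = config or StrategyConfig()
    if set(ds_train.sample_ids) & set(ds_test.sample_ids):
        raise ValueError("train and test sample ids overlap")
    if ds_test.n_events < 2:
        raise ValueError("test split needs at least 2 events")
    res_lasso = run_coxlasso(ds_train, cfg)
    results = {
        "CoxLasso": res_lasso,
        "CoxSis": run_coxsis(ds_train, cfg),
        "CoxSisLasso": run_coxsislasso(ds_train, cfg,
                                       c0=res_lasso.selected_indices),
    }
    if cfg.t_grid is not None:
        t_grid = np.asarray(cfg.t_grid, dtype=float)
    else:
        ev_times = ds_test.time[ds_test.event == 1]
        t_grid = np.unique(np.quantile(ev_times, np.linspace(0.15, 0.85, 8)))
    test_c, test_auc = {}, {}
    for name, res in results.items():
        scores = res.risk_scores(ds_test)
        test_c[name] = cox.concordance(scores, ds_test.time, ds_test.event)
        curve = evaluation.auc_over_time(scores, ds_test.time, ds_test.event,
                                         t_grid, estimator=cfg.estimator)
        test_auc[name] = curve.auc
    overlap = overlap_summary({k: v.selected_ids for k, v in results.items()})
    return ComparisonReport(results, test_c, t_grid, test_auc, overlap)
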