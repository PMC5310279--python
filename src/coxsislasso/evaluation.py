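"""Time-dependent ROC/AUC for censored survival outcomes, and data splitting.

Uses the cumulative-case / dynamic-control definition: at evaluation time t,
cases are subjects with an observed event by t (delta(t) = 1) and controls
are subjects still event-free at t.  Sweeping a cutoff c over the risk
score x'beta traces sensitivity(c, t) = Pr{score > c | case} against
1 - specificity(c, t) = Pr{score > c | control}.

Two estimators are provided: ``naive`` drops subjects censored before t,
while ``km_cd`` reweights cases by the inverse Kaplan--Meier estimate of
the censoring survival function (the cumulative/dynamic construction for
censored data).  With no censoring the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset

__all__ = ["ROCResult", "AUCCurve", "time_dependent_roc", "auc_over_time",
           "train_test_split"]


@dataclass
class ROCResult:
    eval_time: float
    cutoffs: np.ndarray                # decreasing
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    estimator: str


@dataclass
class AUCCurve:
    t_grid: np.ndarray
    auc: np.ndarray          # NaN where the grid point was unusable
    reasons: dict            # t -> reason for a missing value
    estimator: str


def _censoring_km_left(time: np.ndarray, event: np.ndarray,
                       at: np.ndarray) -> np.ndarray:
    """Kaplan--Meier estimate G(u-) of the censoring survival at each u."""
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    cens_s = (1 - event[order]).astype(float)
    n = len(t_s)
    uniq, start = np.unique(t_s, return_index=True)
    counts = np.r_[start[1:], n] - start
    at_risk = n - start
    d_c = np.add.reduceat(cens_s, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d_c / at_risk
    surv = np.cumprod(factors)
    # G(u-) = product over censoring times strictly below u
    idx = np.searchsorted(uniq, at, side="left") - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
    return out


def time_dependent_roc(score, time, event, t: float,
                       estimator: str = "km_cd") -> ROCResult:
    """ROC curve and AUC at a single evaluation time ``t``.

    Cutoffs sweep the unique observed scores plus +/- infinity so the curve
    runs from (0, 0) to (1, 1); the AUC is the trapezoidal area under the
    resulting polyline.
    """
    s = np.asarray(score, dtype=float)
    tm = np.asarray(time, dtype=float)
    ev = np.asarray(event).astype(int)
    if estimator not in ("km_cd", "naive"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if not tm.min() <= t <= tm.max():
        raise ValueError(f"evaluation time {t} outside observed follow-up "
                         f"[{tm.min():g}, {tm.max():g}]")
    case = (tm <= t) & (ev == 1)
    ctrl = tm > t
    if case.sum() == 0:
        raise ValueError(f"no cases (events by t={t:g})")
    if ctrl.sum() == 0:
        raise ValueError(f"no controls (event-free past t={t:g})")
    if estimator == "km_cd":
        g = _censoring_km_left(tm, ev, tm)
        if np.any(g[case] <= 0):
            raise ValueError("censoring-survival estimate vanishes before "
                             "an observed case; km_cd weights undefined")
        w_case = np.where(case, 1.0 / g, 0.0)
    else:
        w_case = case.astype(float)
    w_ctrl = ctrl.astype(float)

    cutoffs = np.r_[np.inf, np.sort(np.unique(s))[::-1], -np.inf]
    above = s[None, :] > cutoffs[:, None]
    sens = (above * w_case).sum(axis=1) / w_case.sum()
    fpr = (above * w_ctrl).sum(axis=1) / w_ctrl.sum()
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(float(t), cutoffs, sens, fpr, auc, estimator)


def auc_over_time(score, time, event, t_grid,
                  estimator: str = "km_cd") -> AUCCurve:
    """AUC(t) over a grid; unusable grid points become NaN with a reason."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be nonempty and strictly increasing")
    aucs = np.full(t_grid.shape, np.nan)
    reasons: dict = {}
    for i, t in enumerate(t_grid):
        try:
            aucs[i] = time_dependent_roc(score, time, event, t, estimator).auc
        except ValueError as exc:
            reasons[float(t)] = str(exc)
    if np.all(np.isnan(aucs)):
        raise ValueError(f"no usable grid point: {reasons}")
    return AUCCurve(t_grid, aucs, reasons, estimator)


def train_test_split(ds: SurvivalDataset, n_train: int, seed: int):
    """Seeded uniform split without replacement; test is the complement.

    Redraws (up to 20 times) until both halves retain at least 2 events.
    """
    if not 2 <= n_train <= ds.n - 2:
        raise ValueError(f"n_train must lie in [2, n-2]; got {n_train}")
    rng = np.random.default_rng(seed)
    for _ in range(20):
        tr = np.sort(rng.choice(ds.n, size=n_train, replace=False))
        te = np.setdiff1d(np.arange(ds.n), tr)
        if ds.event[tr].sum() >= 2 and ds.event[te].sum() >= 2:
            return ds.subset_samples(tr), ds.subset_samples(te)
    raise ValueError("could not split with >= 2 events in both halves")
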