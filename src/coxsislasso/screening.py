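"""Sure independence screening for the Cox model.

Marginal screening fits a one-covariate Cox model per feature and keeps the
d features of largest |beta_m| (the set Theta).  Conditional screening,
given a prior set C0 (typically a Lasso selection), refits the Cox model on
C0 plus each remaining candidate jointly and keeps the candidates whose
Wald z-test p-value falls below a threshold gamma; the operating default is
gamma = 1/p with p the total number of covariates.  Marginal screening can
miss covariates that are jointly predictive but marginally null ("hidden"
covariates); the conditional screen is designed to recover them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cox import CoxSingularError, SurvOrder, _revcumsum, newton_cox
from .data import SurvivalDataset

__all__ = [
    "ScreeningResult",
    "marginal_screen",
    "conditional_screen",
    "default_d",
    "gamma_rule",
]


@dataclass
class ScreeningResult:
    """Outcome of a marginal or conditional screen."""

    mode: str                      # "marginal" | "conditional"
    candidate_indices: np.ndarray  # feature indices examined
    candidate_ids: list
    statistic: np.ndarray          # |beta_m| (marginal) or Wald p (conditional)
    selected_indices: np.ndarray
    selected_ids: list
    d_or_gamma: float
    conditioning_indices: np.ndarray
    conditioning_ids: list
    log: list = field(default_factory=list)


def default_d(n: int) -> int:
    """Screening budget floor(n / log n) from the screening literature."""
    if n < 8:
        raise ValueError("need n >= 8 for a meaningful screening budget")
    return int(n / math.log(n))


def gamma_rule(p_total: int) -> float:
    """Conditional-screening threshold gamma = 1 / p_total."""
    if p_total < 1:
        raise ValueError("p_total must be >= 1")
    return 1.0 / p_total


def _marginal_betas(ds: SurvivalDataset, max_iter: int = 50,
                    chunk: int = 2000):
    """Vectorized one-covariate Cox MLEs for every feature.

    Runs a damped Newton iteration for all features simultaneously (each
    problem is one-dimensional).  Returns (beta, converged) arrays.
    """
    so = SurvOrder(ds.time, ds.event)
    ev = so.ev_mask
    gs_ev = so.group_start[ev]
    beta_all = np.zeros(ds.p)
    conv_all = np.zeros(ds.p, dtype=bool)
    for lo in range(0, ds.p, chunk):
        hi = min(lo + chunk, ds.p)
        Xs = ds.X[so.order, lo:hi]
        k = hi - lo
        beta = np.zeros(k)
        active = np.ones(k, dtype=bool)
        for _ in range(max_iter):
            eta = Xs * beta
            m = eta.max(axis=0)
            w = np.exp(eta - m)
            S0 = _revcumsum(w)
            S1 = _revcumsum(w * Xs)
            S2 = _revcumsum(w * Xs * Xs)
            den = S0[gs_ev]
            xbar = S1[gs_ev] / den
            grad = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
            info = (S2[gs_ev] / den - xbar * xbar).sum(axis=0)
            newly = np.abs(grad) < 1e-8
            active &= ~newly
            if not active.any():
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(info > 1e-12, grad / np.maximum(info, 1e-12), 0.0)
            step = np.clip(step, -2.0, 2.0)  # damping against overshoot
            beta = np.where(active, beta + step, beta)
        conv = ~active | (np.abs(grad) < 1e-6)
        beta_all[lo:hi] = beta
        conv_all[lo:hi] = conv
    return beta_all, conv_all


def marginal_screen(ds: SurvivalDataset, d: int) -> ScreeningResult:
    """Keep the d covariates of largest marginal Cox |beta_m| (the set Theta).

    Ties are broken by original feature order; a feature whose marginal fit
    does not converge is given statistic 0 (never selected) and logged.
    """
    if not 1 <= d <= ds.p:
        raise ValueError(f"d must lie in [1, p={ds.p}]; got {d}")
    beta, conv = _marginal_betas(ds)
    log = [f"marginal fit did not converge for feature {ds.feature_ids[j]}; "
           "statistic set to 0" for j in np.flatnonzero(~conv)]
    stat = np.where(conv, np.abs(beta), 0.0)
    order = np.argsort(-stat, kind="stable")
    selected = np.sort(order[:d])
    return ScreeningResult(
        mode="marginal",
        candidate_indices=np.arange(ds.p),
        candidate_ids=list(ds.feature_ids),
        statistic=stat,
        selected_indices=selected,
        selected_ids=[ds.feature_ids[j] for j in selected],
        d_or_gamma=float(d),
        conditioning_indices=np.empty(0, dtype=np.int64),
        conditioning_ids=[],
        log=log,
    )


def conditional_screen(
    ds: SurvivalDataset,
    conditioning_set,
    gamma: float,
    mode: str = "pvalue",
) -> ScreeningResult:
    """Screen candidates by their significance conditioned on a prior set C0.

    For every m not in C0 the Cox model on C0 + {m} is refit jointly (the C0
    coefficients are re-estimated, not frozen) and the Wald p-value of the
    candidate coefficient is recorded; C1 = {m : p_m < gamma}.  With
    ``mode='magnitude'`` the retention rule is |beta_m| >= gamma instead.
    Candidates whose conditional fit is singular or non-convergent are
    excluded and logged.
    """
    c0 = np.asarray(sorted(set(int(i) for i in conditioning_set)), dtype=np.int64)
    if c0.size == 0:
        raise ValueError("conditioning set C0 must be nonempty")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    if mode not in ("pvalue", "magnitude"):
        raise ValueError(f"unknown mode {mode!r}")
    if c0.size + 1 >= ds.n_events:
        raise ValueError(
            f"|C0|+1 = {c0.size + 1} must be below n_events = {ds.n_events}"
        )
    so = SurvOrder(ds.time, ds.event)
    Xs0 = ds.X[np.ix_(so.order, c0)]
    try:
        beta0, _, _, conv0, _ = newton_cox(
            Xs0, so, feature_ids=[ds.feature_ids[i] for i in c0])
    except CoxSingularError as exc:
        raise CoxSingularError(f"conditioning set C0 is not identifiable: {exc}")
    if not conv0:
        raise ValueError("Cox fit on the conditioning set did not converge")
    candidates = np.setdiff1d(np.arange(ds.p), c0)
    stat = np.full(len(candidates), np.nan)
    log: list = []
    warm = np.r_[beta0, 0.0]
    keep = np.zeros(len(candidates), dtype=bool)
    for i, mfeat in enumerate(candidates):
        Xm = np.column_stack([Xs0, ds.X[so.order, mfeat]])
        try:
            beta, se, _, conv, _ = newton_cox(
                Xm, so, beta0=warm, max_iter=60,
                feature_ids=[ds.feature_ids[j] for j in c0]
                + [ds.feature_ids[mfeat]])
        except CoxSingularError:
            log.append(f"conditional fit singular for feature "
                       f"{ds.feature_ids[mfeat]}; excluded")
            continue
        if not conv or not np.isfinite(se[-1]) or se[-1] <= 0:
            log.append(f"conditional fit did not converge for feature "
                       f"{ds.feature_ids[mfeat]}; excluded")
            continue
        if mode == "pvalue":
            stat[i] = 2.0 * stats.norm.sf(abs(beta[-1] / se[-1]))
            keep[i] = stat[i] < gamma
        else:
            stat[i] = abs(beta[-1])
            keep[i] = stat[i] >= gamma
    selected = candidates[keep]
    return ScreeningResult(
        mode="conditional",
        candidate_indices=candidates,
        candidate_ids=[ds.feature_ids[j] for j in candidates],
        statistic=stat,
        selected_indices=selected,
        selected_ids=[ds.feature_ids[j] for j in selected],
        d_or_gamma=float(gamma),
        conditioning_indices=c0,
        conditioning_ids=[ds.feature_ids[j] for j in c0],
        log=log,
    )
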