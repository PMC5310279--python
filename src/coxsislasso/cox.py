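"""Unpenalized Cox proportional-hazards machinery.

Implements the log partial likelihood and its exact derivatives under the
Breslow convention for tied event times (tied events share one risk set,
each contributing its own event term), a Newton--Raphson fitter with
step-halving, Wald tests, Harrell's concordance index and the Cox--Snell
generalized R^2.

The hazard model is h_i(t) = h0(t) exp(x_i' beta); estimation maximizes

    l(beta) = sum_{k in D} [ x_k' beta - log sum_{j in R_k} exp(x_j' beta) ]

with D the event indices and R_k = {j : t_j >= t_k} the risk set.  The
per-risk-set exponentials are max-shifted before summation so overflow
cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .data import SurvivalDataset

__all__ = [
    "CoxFit",
    "WaldReport",
    "CoxSingularError",
    "partial_loglik",
    "fit_cox",
    "wald_report",
    "concordance",
    "generalized_r2",
    "format_report",
]


class CoxSingularError(np.linalg.LinAlgError):
    """Raised when the observed information is singular (collinear design)."""


# ---------------------------------------------------------------------------
# risk-set bookkeeping


class SurvOrder:
    """Precomputed ascending-time ordering and tie-group boundaries.

    For sorted position i, the risk set of an event at that time is the
    suffix starting at ``group_start[i]`` (ties share a risk set).
    """

    __slots__ = ("order", "time_sorted", "event_sorted", "group_start",
                 "group_end", "ev_mask", "n_events")

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        self.order = np.argsort(time, kind="stable")
        ts = time[self.order]
        self.time_sorted = ts
        self.event_sorted = event[self.order].astype(np.int64)
        new = np.r_[True, ts[1:] != ts[:-1]]
        gidx = np.cumsum(new) - 1
        starts = np.flatnonzero(new)
        ends = np.r_[starts[1:], len(ts)] - 1
        self.group_start = starts[gidx]
        self.group_end = ends[gidx]
        self.ev_mask = self.event_sorted == 1
        self.n_events = int(self.ev_mask.sum())


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def loglik_grad_hess(Xs: np.ndarray, so: SurvOrder, beta: np.ndarray,
                     need_hess: bool = False):
    """Breslow log partial likelihood, gradient and (optionally) Hessian.

    ``Xs`` must already be in ``so.order`` (samples sorted by ascending time).
    Returns (loglik, gradient, hessian-or-None); the Hessian is the second
    derivative of the log likelihood (negative definite at an interior MLE).
    """
    eta = Xs @ beta
    m = eta.max() if eta.size else 0.0
    w = np.exp(eta - m)
    S0 = _revcumsum(w)
    den = S0[so.group_start]
    ev = so.ev_mask
    ll = float(eta[ev].sum() - (m + np.log(den[ev])).sum())
    S1 = _revcumsum(w[:, None] * Xs)
    xbar = S1[so.group_start[ev]] / den[ev, None]
    grad = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
    if not need_hess:
        return ll, grad, None
    # sum_ev S2(gs)/den = X' diag(w * A) X with A_j the cumulative 1/den of
    # the events whose risk set contains j; sum_ev xbar xbar' = xbar' xbar
    inv = ev / den
    A = np.cumsum(inv)[so.group_end]
    info = (Xs * (w * A)[:, None]).T @ Xs - xbar.T @ xbar
    return ll, grad, -info


def _null_loglik(so: SurvOrder) -> float:
    """l(0) = -sum over events of log |R_k|."""
    n = len(so.time_sorted)
    sizes = n - so.group_start[so.ev_mask]
    return float(-np.log(sizes).sum())


# ---------------------------------------------------------------------------
# Newton fitting


@dataclass
class CoxFit:
    """Unpenalized Cox fit on a feature subset."""

    feature_ids: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_samples: int
    n_events: int
    converged: bool
    iterations: int


@dataclass
class WaldReport:
    """Per-feature Wald z statistics, two-sided p-values and hazard ratios."""

    feature_ids: list
    z: np.ndarray
    p_value: np.ndarray
    hazard_ratio: np.ndarray


def _collinear_names(Xs: np.ndarray, feature_ids) -> list:
    """Name columns implicated in exact/near collinearity via pivoted QR."""
    Xc = Xs - Xs.mean(axis=0)
    _q, r, piv = sla.qr(Xc, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(Xc.shape) * np.finfo(float).eps if d.size else 0.0
    bad = piv[np.flatnonzero(d <= tol)] if d.size else []
    return [feature_ids[j] for j in sorted(bad)]


def newton_cox(Xs: np.ndarray, so: SurvOrder, beta0: np.ndarray | None = None,
               max_iter: int = 100, grad_tol: float = 1e-8,
               ll_rtol: float = 1e-10, feature_ids=None):
    """Newton--Raphson with step-halving on the Breslow partial likelihood.

    ``Xs`` in sorted-sample order.  Returns (beta, se, loglik, converged,
    iterations).  Raises :class:`CoxSingularError` on a singular information
    matrix.
    """
    k = Xs.shape[1]
    ids = list(feature_ids) if feature_ids is not None else list(range(k))
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = loglik_grad_hess(Xs, so, beta, need_hess=True)
    converged = False
    it = 0
    while it < max_iter:
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        it += 1
        info = -hess
        try:
            c, low = sla.cho_factor(info)
            step = sla.cho_solve((c, low), grad)
        except (sla.LinAlgError, ValueError) as exc:
            names = _collinear_names(Xs, ids)
            raise CoxSingularError(
                "singular information matrix; collinear features: "
                f"{names if names else ids}"
            ) from exc
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new, grad_new, hess_new = loglik_grad_hess(Xs, so, cand,
                                                          need_hess=True)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover - step-halving exhausted
            break
        done = abs(ll_new - ll) < ll_rtol * (abs(ll) + 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if done:
            # a flattening likelihood with runaway coefficients signals
            # monotone likelihood (separation), not convergence
            converged = bool(np.max(np.abs(beta)) < 1e2)
            break
    info = -hess
    try:
        c, low = sla.cho_factor(info)
        cov = sla.cho_solve((c, low), np.eye(k))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except (sla.LinAlgError, ValueError) as exc:
        names = _collinear_names(Xs, ids)
        raise CoxSingularError(
            f"singular information matrix at the optimum; collinear features: "
            f"{names if names else ids}"
        ) from exc
    return beta, se, ll, converged, it


def _resolve_features(ds: SurvivalDataset, features):
    if features is None:
        return np.arange(ds.p)
    return np.asarray(list(features), dtype=np.int64)


def partial_loglik(ds: SurvivalDataset, features, beta):
    """Log partial likelihood and its gradient at ``beta``.

    ``features`` indexes columns of ``ds.X``; ``beta`` has matching length.
    """
    idx = _resolve_features(ds, features)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(idx),):
        raise ValueError("beta length must match the feature subset")
    so = SurvOrder(ds.time, ds.event)
    if ds.n_events < 1:
        raise ValueError("dataset has no events")
    Xs = ds.X[np.ix_(so.order, idx)]
    ll, grad, _ = loglik_grad_hess(Xs, so, beta)
    if not np.isfinite(ll):  # pragma: no cover - max-shift makes this unreachable
        raise FloatingPointError(
            "partial likelihood overflow; center covariates before fitting"
        )
    return ll, grad


def fit_cox(ds: SurvivalDataset, features=None, max_iter: int = 100) -> CoxFit:
    """Maximum partial-likelihood fit on a feature subset.

    Newton--Raphson from beta = 0 with step-halving; converged when the
    max |gradient| drops below 1e-8 or the relative log-likelihood change
    below 1e-10.  Standard errors come from the inverse observed information
    at the optimum.
    """
    idx = _resolve_features(ds, features)
    so = SurvOrder(ds.time, ds.event)
    ll0 = _null_loglik(so)
    ids = [ds.feature_ids[i] for i in idx]
    if len(idx) == 0:
        return CoxFit(ids, np.empty(0), np.empty(0), ll0, ll0,
                      ds.n, ds.n_events, True, 0)
    if len(idx) >= ds.n_events:
        raise ValueError(
            f"{len(idx)} features with only {ds.n_events} events; "
            "need |features| < n_events for identifiability"
        )
    Xs = ds.X[np.ix_(so.order, idx)]
    const = np.flatnonzero(Xs.std(axis=0) == 0)
    if const.size:
        raise ValueError(
            f"constant covariate column(s): {[ids[j] for j in const]}"
        )
    beta, se, ll, converged, it = newton_cox(Xs, so, max_iter=max_iter,
                                             feature_ids=ids)
    return CoxFit(ids, beta, se, ll, ll0, ds.n, ds.n_events, converged, it)


def wald_report(fit: CoxFit) -> WaldReport:
    """Wald z = beta/se, two-sided normal p-values, hazard ratios exp(beta)."""
    if not np.all(np.isfinite(fit.se)):
        raise ValueError("non-finite standard errors; Wald test undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(fit.se > 0, fit.beta / fit.se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return WaldReport(list(fit.feature_ids), z, p, np.exp(fit.beta))


def concordance(risk_score, time, event) -> float:
    """Harrell's concordance index.

    A pair (i, j) is permissible iff the strictly earlier time is an event;
    it is concordant when the shorter survivor has the higher risk score;
    score ties score half credit.
    """
    s = np.asarray(risk_score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("risk_score, time and event must have equal length")
    perm = (t[:, None] < t[None, :]) & e[:, None]
    n_perm = int(perm.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs (check events and time spread)")
    gt = s[:, None] > s[None, :]
    eq = s[:, None] == s[None, :]
    conc = gt[perm].sum() + 0.5 * eq[perm].sum()
    return float(conc / n_perm)


def generalized_r2(fit: CoxFit) -> float:
    """Cox--Snell generalized R^2 = 1 - exp(-(2/n)(l(beta) - l(0)))."""
    return float(1.0 - np.exp(-2.0 / fit.n_samples
                              * (fit.loglik - fit.loglik_null)))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_report(fit: CoxFit, r2: float | None = None,
                  concordance_value: float | None = None) -> str:
    """Plain-text fit summary: coef, exp(coef), se(coef), z, p-value + stars."""
    wald = wald_report(fit)
    width = max([len(str(f)) for f in fit.feature_ids] + [8])
    lines = [f"{'feature':<{width}} {'coef':>10} {'exp(coef)':>10} "
             f"{'se(coef)':>10} {'z':>8} {'p-value':>10}"]
    for i, fid in enumerate(fit.feature_ids):
        lines.append(
            f"{str(fid):<{width}} {fit.beta[i]:>10.5f} "
            f"{wald.hazard_ratio[i]:>10.5f} {fit.se[i]:>10.5f} "
            f"{wald.z[i]:>8.3f} {wald.p_value[i]:>10.4g} {_stars(wald.p_value[i])}"
        )
    if r2 is not None and concordance_value is not None:
        lines.append(f"R^2 = {r2:.3f}, Concordance = {concordance_value:.3f}")
    lines.append("Significance codes: 0 '***' 0.001 '**' 0.01 '*' 0.05")
    return "\n".join(lines)
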