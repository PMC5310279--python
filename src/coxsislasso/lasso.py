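"""L1-penalized Cox regression: regularization path and cross-validation.

Solves, over a decreasing lambda grid,

    min_beta  -(1/n) l(beta) + lambda * sum_j |beta_j|

with l the Breslow log partial likelihood, by the standard penalized-IRLS
scheme: at the current linear predictor the likelihood is replaced by its
diagonal-Hessian weighted least-squares approximation and cyclic coordinate
descent is run on an active set, with exact-gradient KKT checks deciding
which coordinates may enter.  Covariates are standardized (mean 0, unit
variance) internally; coefficients are reported on the original scale.

Lambda selection uses the cross-validated partial-likelihood deviance in the
Verweij--van Houwelingen form: the contribution of fold k at a given lambda
is -2 [ l_full(beta_{-k}) - l_{-k}(beta_{-k}) ], i.e. the predictive part of
the full-data likelihood not explained by the training portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cox import SurvOrder, _revcumsum, loglik_grad_hess
from .data import SurvivalDataset

__all__ = [
    "LassoPath",
    "CVResult",
    "lambda_max",
    "fit_lasso_path",
    "cv_select_lambda",
    "lasso_select",
    "kkt_residuals",
]

_INNER_TOL = 1e-10
_OUTER_TOL = 1e-7
_KKT_ENTER = 1e-7
_KKT_ACCEPT = 1e-5


@dataclass
class LassoPath:
    """Penalized solutions over a decreasing lambda grid."""

    lambdas: np.ndarray
    coefs: np.ndarray       # (n_lambda, p), original covariate scale
    coefs_std: np.ndarray   # (n_lambda, p), standardized scale (internal)
    nonzero_counts: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    feature_ids: list


@dataclass
class CVResult:
    """Cross-validation curve and the selected penalty."""

    lambdas: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    fold_assignment_seed: int
    fold_ids: np.ndarray
    path: LassoPath


def _standardize(ds: SurvivalDataset):
    center = ds.X.mean(axis=0)
    scale = ds.X.std(axis=0)
    bad = np.flatnonzero((scale == 0) | (np.ptp(ds.X, axis=0) == 0))
    if bad.size:
        raise ValueError(
            "constant covariate(s) cannot be standardized: "
            f"{[ds.feature_ids[j] for j in bad[:10]]}"
        )
    return (ds.X - center) / scale, center, scale


def _score_eta(eta: np.ndarray, so: SurvOrder):
    """Score u = dl/deta and diagonal weights d = -d2l/deta^2 (sorted frame)."""
    m = eta.max()
    w = np.exp(eta - m)
    S0 = _revcumsum(w)
    den = S0[so.group_start]
    ev = so.ev_mask.astype(float)
    inv = ev / den
    A = np.cumsum(inv)[so.group_end]
    B = np.cumsum(inv / den)[so.group_end]
    u = ev - w * A
    d = w * A - w * w * B
    return u, d


def _loglik_eta(eta: np.ndarray, so: SurvOrder) -> np.ndarray:
    """Breslow log partial likelihood for each column of an eta matrix."""
    eta = np.atleast_2d(eta.T).T  # (n, L)
    m = eta.max(axis=0)
    w = np.exp(eta - m)
    S0 = _revcumsum(w)
    den = S0[so.group_start]
    ev = so.ev_mask
    return eta[ev].sum(axis=0) - (m + np.log(den[ev])).sum(axis=0)


def lambda_max(ds: SurvivalDataset) -> float:
    """Smallest penalty at which the all-zero solution is optimal.

    Equals max_j |g_j(0)| / n with g the partial-likelihood gradient at
    beta = 0 on the standardized covariates (the KKT boundary).
    """
    Xstd, _, _ = _standardize(ds)
    so = SurvOrder(ds.time, ds.event)
    Xs = Xstd[so.order]
    u, _ = _score_eta(np.zeros(ds.n), so)
    g = Xs.T @ u / ds.n
    return float(np.max(np.abs(g)))


def _soft(x: float, lam: float) -> float:
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0


def _solve_wls_lasso(G, b, lam, beta0):
    """Exact minimizer of (1/2) b'Gb - b'beta + lam*|beta|_1 by active sets.

    Feature-sign search: solve the quadratic restricted to the current sign
    pattern, clip the first coefficient that crosses zero along the way, and
    admit the worst KKT violator among the zeros until none remains.  ``G``
    must be positive definite on every active subset encountered.
    """
    m = len(b)
    beta = np.asarray(beta0, dtype=float).copy()
    if m == 0:
        return beta
    for _it in range(20 * m + 40):
        active = np.flatnonzero(beta)
        if active.size == 0:
            j = int(np.argmax(np.abs(b)))
            if abs(b[j]) <= lam * (1 + 1e-12) + 1e-15:
                return beta
            beta[j] = np.sign(b[j]) * 1e-300  # enter with the right sign
            continue
        s = np.sign(beta[active])
        rhs = b[active] - lam * s
        try:
            x = np.linalg.solve(G[np.ix_(active, active)], rhs)
        except np.linalg.LinAlgError:
            x, *_ = np.linalg.lstsq(G[np.ix_(active, active)], rhs, rcond=None)
        flipped = np.flatnonzero(np.sign(x) != s)
        if flipped.size:
            xa = beta[active]
            denom = xa[flipped] - x[flipped]
            with np.errstate(divide="ignore", invalid="ignore"):
                tj = np.where(np.abs(denom) > 0, xa[flipped] / denom, 0.0)
            tj = np.where((tj > 0) & (tj <= 1), tj, np.inf)
            t = float(np.min(tj)) if np.isfinite(np.min(tj)) else 1.0
            beta[active] = xa + t * (x - xa)
            beta[active[np.abs(beta[active]) < 1e-14]] = 0.0
            # the coefficient that hit zero leaves the active set
            beta[active[flipped[np.argmin(tj)]]] = 0.0
            continue
        beta[:] = 0.0
        beta[active] = x
        g = G @ beta - b
        zero = beta == 0
        if not zero.any():
            return beta
        viol = np.abs(g[zero]) - lam
        jz = int(np.argmax(viol))
        if viol[jz] <= 1e-12:
            return beta
        j = np.flatnonzero(zero)[jz]
        beta[j] = -np.sign(g[j]) * 1e-300
    raise RuntimeError("penalized weighted-least-squares solve cycled")


def _polish_active(Xs, so, n, beta, lam):
    """Full-Hessian Newton on the sign-restricted active set.

    With the signs s of the active coefficients fixed, the objective
    -(1/n) l(beta_A) + lam * s' beta_A is smooth; Newton steps (with
    step-halving and zero-crossing clipping) drive the stationarity
    residual to machine precision.  Coefficients that hit zero leave the
    active set.
    """
    for _it in range(60):
        A = np.flatnonzero(beta)
        if A.size == 0:
            return
        s = np.sign(beta[A])
        XA = Xs[:, A]
        ll, grad, hess = loglik_grad_hess(XA, so, beta[A], need_hess=True)
        gpen = -grad / n + lam * s
        if np.max(np.abs(gpen)) < 1e-10:
            return
        info = -hess / n
        try:
            step = np.linalg.solve(info, -gpen)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(info, -gpen, rcond=None)
        f0 = -ll / n + lam * float(s @ beta[A])
        # furthest step before any active coefficient changes sign
        crossing = step * s < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            tcap = np.where(crossing, -beta[A] / step, np.inf)
        tmax = float(np.min(tcap, initial=np.inf))
        t = min(1.0, tmax)
        improved = False
        for _half in range(40):
            cand = beta[A] + t * step
            llc, _, _ = loglik_grad_hess(XA, so, cand, need_hess=False)
            fc = -llc / n + lam * float(s @ cand)
            if np.isfinite(fc) and fc <= f0 + 1e-14:
                improved = True
                break
            t *= 0.5
        if not improved:
            return
        beta[A] = beta[A] + t * step
        if t == tmax:  # a coefficient reached zero: drop it exactly
            beta[A[np.abs(beta[A]) < 1e-13]] = 0.0


def _solve_at_lambda(Xs, Xs2, so, n, beta, lam, ever_active):
    """Penalized IRLS at one lambda, warm-started in place.

    Each outer iteration replaces the partial likelihood by its weighted
    least-squares approximation at the current linear predictor and solves
    that subproblem exactly.  Returns the exact-gradient vector at the
    solution (for KKT bookkeeping); raises RuntimeError on non-convergence.
    """
    for _entry_round in range(100):
        elig = np.flatnonzero(ever_active)
        outer_ok = elig.size == 0
        for _outer in range(5 if elig.size else 0):
            eta = Xs[:, elig] @ beta[elig] if elig.size else np.zeros(n)
            u, d = _score_eta(eta, so)
            with np.errstate(invalid="ignore", divide="ignore"):
                zres = np.where(d > 1e-12, u / np.maximum(d, 1e-12), 0.0)
            Xe = Xs[:, elig]
            Xd = Xe * d[:, None]
            G = Xd.T @ Xe / n
            bvec = (Xd.T @ (eta + zres)) / n
            # absorb the quadratic cross-terms: grad of the WLS fit at beta
            beta_new = _solve_wls_lasso(G, bvec, lam, beta[elig])
            delta = np.max(np.abs(beta_new - beta[elig])) if elig.size else 0.0
            beta[elig] = beta_new
            if delta < _OUTER_TOL:
                outer_ok = True
                break
        _polish_active(Xs, so, n, beta, lam)
        # exact-gradient KKT check over all coordinates is the authority:
        # accept when every residual is within tolerance, else grow the set
        nz = np.flatnonzero(beta)
        eta = Xs[:, nz] @ beta[nz] if nz.size else np.zeros(n)
        u, _ = _score_eta(eta, so)
        g = Xs.T @ u / n
        viol = np.flatnonzero((np.abs(g) > lam + _KKT_ENTER) & (beta == 0))
        if viol.size:
            ever_active[viol] = True
            continue
        worst = 0.0
        if nz.size:
            worst = float(np.max(np.abs(g[nz] - lam * np.sign(beta[nz]))))
        if worst <= _KKT_ACCEPT and (outer_ok or worst <= 1e-8):
            return g
        raise RuntimeError(
            f"penalized fit did not converge at lambda={lam:g} "
            f"(KKT residual {worst:g})"
        )
    raise RuntimeError(  # pragma: no cover - entry rounds exhausted
        f"active-set growth did not terminate at lambda={lam:g}")


def _lambda_grid(lam_max, n_lambda, ratio):
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * ratio), n_lambda))


def fit_lasso_path(
    ds: SurvivalDataset,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: np.ndarray | None = None,
) -> LassoPath:
    """Solve the penalized Cox problem over a log-spaced lambda grid.

    The grid runs from ``lambda_max`` down to ``lambda_max * lambda_min_ratio``
    (default 0.01 when p > n, else 1e-4); each solution warm-starts the next.
    Every returned solution satisfies the KKT conditions to within 1e-5.
    """
    Xstd, center, scale = _standardize(ds)
    so = SurvOrder(ds.time, ds.event)
    Xs = np.asfortranarray(Xstd[so.order])  # fast column access in the CD loop
    Xs2 = Xs * Xs
    n, p = Xs.shape
    u0, _ = _score_eta(np.zeros(n), so)
    lam_max = float(np.max(np.abs(Xs.T @ u0 / n)))
    if lambdas is None:
        if lambda_min_ratio is None:
            lambda_min_ratio = 0.01 if p > n else 1e-4
        lambdas = _lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
    beta = np.zeros(p)
    ever_active = np.zeros(p, dtype=bool)
    coefs_std = np.zeros((len(lambdas), p))
    for li, lam in enumerate(lambdas):
        if lam >= lam_max:
            continue  # all-zero by the KKT boundary condition
        _solve_at_lambda(Xs, Xs2, so, n, beta, lam, ever_active)
        coefs_std[li] = beta
    coefs = coefs_std / scale
    return LassoPath(
        lambdas=lambdas,
        coefs=coefs,
        coefs_std=coefs_std,
        nonzero_counts=(coefs_std != 0).sum(axis=1),
        center=center,
        scale=scale,
        feature_ids=list(ds.feature_ids),
    )


def kkt_residuals(ds: SurvivalDataset, lam: float, beta_std: np.ndarray):
    """KKT residuals of a standardized-scale solution at penalty ``lam``.

    Returns (slack_zero, stat_active): for zero coefficients the excess
    max(|g_j|/n - lambda, 0); for active ones |g_j/n - lambda * sign(beta_j)|.
    Both should be ~0 at a valid solution.
    """
    Xstd, _, _ = _standardize(ds)
    so = SurvOrder(ds.time, ds.event)
    Xs = Xstd[so.order]
    eta = Xs @ beta_std
    u, _ = _score_eta(eta, so)
    g = Xs.T @ u / ds.n
    zero = beta_std == 0
    slack_zero = np.maximum(np.abs(g[zero]) - lam, 0.0)
    stat_active = np.abs(g[~zero] - lam * np.sign(beta_std[~zero]))
    return slack_zero, stat_active


def _stratified_folds(event: np.ndarray, n_folds: int, rng) -> np.ndarray:
    fold = np.empty(len(event), dtype=np.int64)
    for grp in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(grp)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def cv_select_lambda(
    ds: SurvivalDataset,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    rule: str = "min",
) -> CVResult:
    """Pick lambda by cross-validated partial-likelihood deviance.

    Folds are assigned by a seeded permutation stratified on the event
    indicator.  ``rule='min'`` (default) selects the deviance-minimizing
    lambda; ``rule='1se'`` the largest lambda within one standard error
    of that minimum.
    """
    if not 3 <= n_folds <= ds.n_events:
        raise ValueError(
            f"n_folds must lie in [3, n_events={ds.n_events}]; got {n_folds}"
        )
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(ds.event, n_folds, rng)
    for _redraw in range(2):
        ok = all((ds.event[fold == k] == 1).sum() > 0 for k in range(n_folds))
        if ok:
            break
        fold = _stratified_folds(ds.event, n_folds, rng)
    else:
        raise ValueError("could not form folds with at least one event each")

    path = fit_lasso_path(ds, n_lambda=n_lambda,
                          lambda_min_ratio=lambda_min_ratio)
    lambdas = path.lambdas
    so_full = SurvOrder(ds.time, ds.event)
    X_full_sorted = ds.X[so_full.order]
    dev = np.zeros((n_folds, len(lambdas)))
    for k in range(n_folds):
        tr = np.flatnonzero(fold != k)
        ds_tr = ds.subset_samples(tr)
        path_k = fit_lasso_path(ds_tr, lambdas=lambdas)
        B = path_k.coefs.T  # (p, L) original scale
        so_tr = SurvOrder(ds_tr.time, ds_tr.event)
        ll_full = _loglik_eta(X_full_sorted @ B, so_full)
        ll_tr = _loglik_eta(ds_tr.X[so_tr.order] @ B, so_tr)
        dev[k] = -2.0 * (ll_full - ll_tr)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    imin = int(np.argmin(cv_mean))
    if rule == "min":
        lam_sel = float(lambdas[imin])
    elif rule == "1se":
        ok = cv_mean <= cv_mean[imin] + cv_se[imin]
        lam_sel = float(lambdas[np.flatnonzero(ok)[0]])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return CVResult(lambdas, cv_mean, cv_se, lam_sel, seed, fold, path)


def lasso_select(
    ds: SurvivalDataset,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    rule: str = "min",
) -> np.ndarray:
    """Indices of the nonzero coefficients at the CV-selected lambda (C0)."""
    cv = cv_select_lambda(ds, n_folds=n_folds, seed=seed, n_lambda=n_lambda,
                          lambda_min_ratio=lambda_min_ratio, rule=rule)
    li = int(np.flatnonzero(cv.lambdas == cv.lambda_selected)[0])
    sel = np.flatnonzero(cv.path.coefs_std[li])
    if sel.size == 0:
        warnings.warn("penalized selection is empty at the chosen lambda",
                      stacklevel=2)
    return sel
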