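"""Synthetic high-dimensional expression + survival data from a sparse Cox model.

Covariates are zero-mean unit-variance Gaussian with a configurable
correlation structure (independent, AR(1) or equicorrelated); event times
come from the proportional-hazards model by inverse transform of the
baseline cumulative hazard; censoring times are uniform on (0, c*) with c*
calibrated by bisection so the expected censoring fraction hits a target.

The ``hidden_variable_config`` design makes one truly active covariate
marginally invisible: with equicorrelation rho and actives
beta = (b, b, b, -3*rho*b), Cov(X_4, X' beta) = beta_4 + rho * 3b = 0, so
the fourth covariate is jointly important but uncorrelated with the linear
predictor -- the failure mode of marginal screening that conditional
screening is built to repair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (ExpressionMatrix, GeneSetCollection, SurvivalDataset,
                   SurvivalTable, write_expression, write_gmt, write_survival)

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset",
           "hidden_variable_config", "strong_signal_config",
           "make_gene_sets", "write_dataset_files"]


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic survival study."""

    n: int
    p: int
    support: tuple            # indices of truly active features
    beta_true: tuple          # coefficient per active feature
    correlation: tuple = ("independent",)   # | ("ar1", rho) | ("equicorrelated", rho)
    baseline: tuple = ("exponential", 1.0)  # | ("weibull", shape, scale)
    censoring_rate_target: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.support = tuple(int(i) for i in self.support)
        self.beta_true = tuple(float(b) for b in self.beta_true)
        if len(self.support) != len(self.beta_true):
            raise ValueError("support and beta_true lengths differ")
        if any(not 0 <= i < self.p for i in self.support):
            raise ValueError("support indices out of range")
        kind = self.correlation[0]
        if kind not in ("independent", "ar1", "equicorrelated"):
            raise ValueError(f"unknown correlation kind {kind!r}")
        if kind != "independent" and not 0 <= self.correlation[1] < 1:
            raise ValueError("correlation rho must lie in [0, 1)")
        if self.baseline[0] not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.baseline[0]!r}")
        if not 0 <= self.censoring_rate_target < 1:
            raise ValueError("censoring_rate_target must lie in [0, 1)")


@dataclass
class SimulatedDataset:
    dataset: SurvivalDataset
    truth: SimulationConfig
    latent: np.ndarray                 # x_i' beta_true per sample
    realized_censoring_rate: float


def _draw_covariates(cfg: SimulationConfig, rng) -> np.ndarray:
    z = rng.standard_normal((cfg.n, cfg.p))
    kind = cfg.correlation[0]
    if kind == "independent":
        return z
    rho = float(cfg.correlation[1])
    if kind == "equicorrelated":
        shared = rng.standard_normal((cfg.n, 1))
        return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z
    # AR(1): x_j = rho x_{j-1} + sqrt(1-rho^2) z_j keeps unit variance
    X = np.empty_like(z)
    X[:, 0] = z[:, 0]
    a = np.sqrt(1.0 - rho * rho)
    for j in range(1, cfg.p):
        X[:, j] = rho * X[:, j - 1] + a * z[:, j]
    return X


def _baseline_inverse(cfg: SimulationConfig, u: np.ndarray,
                      eta: np.ndarray) -> np.ndarray:
    """T = H0^{-1}(-log U / exp(eta)) for the configured baseline."""
    arg = -np.log(u) / np.exp(eta)
    if cfg.baseline[0] == "exponential":
        rate = float(cfg.baseline[1])
        return arg / rate
    shape, scale = float(cfg.baseline[1]), float(cfg.baseline[2])
    return scale * arg ** (1.0 / shape)


def _calibrate_censoring_bound(T: np.ndarray, target: float) -> float:
    """Bisect c* so that E[#{C < T}]/n = target for C ~ U(0, c*)."""
    def rate(c):  # P(censored_i) = min(T_i / c, 1)
        return float(np.minimum(T / c, 1.0).mean())

    lo, hi = float(np.min(T)) * 1e-6, float(np.max(T))
    while rate(hi) > target:
        hi *= 2.0
        if hi > 1e300:
            raise ValueError(f"censoring target {target} unachievable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the configured sparse Cox model (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    X = _draw_covariates(cfg, rng)
    eta = X[:, list(cfg.support)] @ np.asarray(cfg.beta_true) \
        if cfg.support else np.zeros(cfg.n)
    u = rng.uniform(size=cfg.n)
    T = _baseline_inverse(cfg, u, eta)
    T = np.maximum(T, np.finfo(float).tiny)
    if cfg.censoring_rate_target > 0:
        cstar = _calibrate_censoring_bound(T, cfg.censoring_rate_target)
        C = rng.uniform(0.0, cstar, size=cfg.n)
        time = np.minimum(T, C)
        event = (T <= C).astype(np.int64)
    else:
        time, event = T, np.ones(cfg.n, dtype=np.int64)
    width = max(5, len(str(cfg.p)))
    feature_ids = [f"G{j + 1:0{width}d}" for j in range(cfg.p)]
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n)]
    ds = SurvivalDataset(X=X, time=time, event=event,
                         feature_ids=feature_ids, sample_ids=sample_ids)
    return SimulatedDataset(ds, cfg, eta,
                            float(1.0 - event.mean()))


def strong_signal_config(n: int = 300, p: int = 500, n_active: int = 5,
                         beta0: float = 1.0, rho: float = 0.5,
                         censoring: float = 0.25,
                         seed: int = 0) -> SimulationConfig:
    """AR(1)-correlated design with a handful of strong, spread-out effects."""
    support = tuple(np.linspace(0, p - 1, n_active, dtype=int))
    signs = [1.0 if i % 2 == 0 else -1.0 for i in range(n_active)]
    return SimulationConfig(
        n=n, p=p, support=support,
        beta_true=tuple(beta0 * s for s in signs),
        correlation=("ar1", rho),
        censoring_rate_target=censoring,
        seed=seed,
    )


def hidden_variable_config(n: int, p: int, rho: float, beta0: float,
                           seed: int,
                           censoring: float = 0.25) -> SimulationConfig:
    """Equicorrelated design whose fourth active covariate is marginally null.

    support = {0,1,2,3} with beta = (b0, b0, b0, -3*rho*b0), so
    Cov(X_4, X' beta) = beta_4 + rho * 3 b0 = 0 exactly.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if beta0 == 0:
        raise ValueError("beta0 must be nonzero")
    return SimulationConfig(
        n=n, p=p, support=(0, 1, 2, 3),
        beta_true=(beta0, beta0, beta0, -3.0 * rho * beta0),
        correlation=("equicorrelated", rho),
        censoring_rate_target=censoring,
        seed=seed,
    )


def make_gene_sets(feature_ids, support_ids, n_sets: int = 20,
                   set_size: int = 15, seed: int = 0) -> GeneSetCollection:
    """Random gene sets plus one set enriched for the true support."""
    rng = np.random.default_rng(seed)
    ids = list(feature_ids)
    support_ids = list(support_ids)
    sets: dict = {}
    fill = [g for g in ids if g not in set(support_ids)]
    extra = rng.choice(len(fill), size=max(0, set_size - len(support_ids)),
                       replace=False)
    truth = support_ids + [fill[i] for i in extra]
    sets["PATHWAY_TRUE"] = ("contains the truly active genes", truth)
    for s in range(n_sets - 1):
        members = rng.choice(len(ids), size=set_size, replace=False)
        sets[f"PATHWAY_{s + 1:03d}"] = ("random gene set",
                                        [ids[i] for i in members])
    return GeneSetCollection(sets)


def write_dataset_files(sim: SimulatedDataset, outdir,
                        gene_sets: GeneSetCollection | None = None) -> dict:
    """Emit expression TSV, survival CSV (+ optional GMT) pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = sim.dataset
    paths = {
        "expression": outdir / "expression.tsv",
        "survival": outdir / "survival.csv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(
        ExpressionMatrix(ds.X.T, ds.feature_ids, ds.sample_ids),
        paths["expression"],
    )
    write_survival(SurvivalTable(ds.sample_ids, ds.time, ds.event),
                   paths["survival"])
    with open(paths["truth"], "w") as fh:
        fh.write("feature_id\tbeta_true\n")
        for i, b in zip(sim.truth.support, sim.truth.beta_true):
            fh.write(f"{ds.feature_ids[i]}\t{b:g}\n")
    if gene_sets is not None:
        paths["gene_sets"] = outdir / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gene_sets"])
    return paths
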