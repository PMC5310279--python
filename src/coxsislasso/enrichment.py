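"""Hypergeometric over-representation analysis of a selected gene set.

Given a selection of n genes from a universe of N, a gene set with K
members in the universe and an overlap of k, the enrichment p-value is the
upper tail P(X >= k) of the hypergeometric pmf

    P(X = k) = C(K, k) C(N-K, n-k) / C(N, n),

evaluated in log-space for overflow safety.  This is the standard local
stand-in for pathway-database enrichment queries; any GMT collection
(e.g. an exported KEGG snapshot) supplies the gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_pmf", "hypergeom_tail", "enrich",
           "adjust_pvalues"]


@dataclass
class EnrichmentResult:
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    p_adjusted: float
    overlap_ids: list


_LOGFACT = np.zeros(1)


def _logfact(m: int) -> float:
    """log(m!) from a lazily grown lookup table (log-gamma identity)."""
    global _LOGFACT
    if m >= len(_LOGFACT):
        _LOGFACT = gammaln(np.arange(max(m + 1, 2 * len(_LOGFACT))) + 1.0)
    return float(_LOGFACT[m])


def _log_choose(a: int, b: int) -> float:
    return _logfact(a) - _logfact(b) - _logfact(a - b)


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for k successes in n draws from N with K success states.

    Out-of-support k returns 0 (so tail sums need no bounds fiddling);
    invalid (N, K, n) raises.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0
    return float(np.exp(_log_choose(K, k) + _log_choose(N - K, n - k)
                        - _log_choose(N, n)))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k)."""
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    return float(min(1.0, sum(hypergeom_pmf(N, K, n, j)
                              for j in range(k, hi + 1))))


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment (input order preserved, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in key:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key[method])[1]


def enrich(selected, sets: GeneSetCollection, universe,
           method: str = "benjamini_hochberg") -> list:
    """Over-representation test of ``selected`` against every gene set.

    Genes outside the universe are dropped with a warning; sets with no
    member in the universe are skipped.  Results are sorted by p-value
    ascending (ties by set name), with adjusted p-values across the tested
    sets.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must be nonempty")
    uni = set(universe)
    selected = list(dict.fromkeys(selected))
    if not selected:
        raise ValueError("selected gene list is empty")
    outside = [g for g in selected if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} selected gene(s) outside the universe "
                      f"dropped: {outside[:5]}", stacklevel=2)
    sel = [g for g in selected if g in uni]
    if not sel:
        raise ValueError("no selected gene lies in the universe")
    N, n = len(uni), len(sel)
    sel_set = set(sel)
    rows = []
    for name, (_desc, members) in sets.sets.items():
        in_uni = [g for g in members if g in uni]
        K = len(in_uni)
        if K == 0:
            continue
        overlap = [g for g in in_uni if g in sel_set]
        k = len(overlap)
        rows.append((name, K, k, overlap, hypergeom_tail(N, K, n, k)))
    rows.sort(key=lambda r: (r[4], r[0]))
    padj = adjust_pvalues([r[4] for r in rows], method=method) if rows else []
    return [
        EnrichmentResult(name, N, K, n, k, p, float(pa), overlap)
        for (name, K, k, overlap, p), pa in zip(rows, padj)
    ]
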