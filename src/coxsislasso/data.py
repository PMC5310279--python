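"""Input containers and I/O for expression + survival + gene-set data.

The canonical in-memory object is :class:`SurvivalDataset`: a samples x
features covariate matrix aligned with a follow-up time and an event
indicator per sample.  Expression matrices on disk follow the microarray
convention (features in rows, samples in columns); internally everything is
rows-as-subjects, matching the regression notation ``x_i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "SurvivalDataset",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_gmt",
    "write_gmt",
    "assemble_dataset",
    "iqr_filter",
]


def _check_unique(labels, kind: str) -> None:
    seen: dict = {}
    dups = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen[lab] = True
    if dups:
        raise ValueError(f"duplicate {kind}: {sorted(set(map(str, dups)))}")


@dataclass
class ExpressionMatrix:
    """Expression values, features x samples."""

    values: np.ndarray
    feature_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite expression value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1=event, 0=censored)."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        _check_unique(self.sample_ids, "sample ids")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all follow-up times must be positive and finite")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(np.int64)


@dataclass
class SurvivalDataset:
    """Aligned covariates (n samples x p features) + survival outcome."""

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_ids: list
    sample_ids: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int64)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("id lists inconsistent with X shape")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length inconsistent with X")
        if np.any(self.time <= 0):
            raise ValueError("all follow-up times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if int(self.event.sum()) < 2:
            raise ValueError(
                "need at least 2 observed events for Cox fitting; got "
                f"{int(self.event.sum())}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset_features(self, indices) -> "SurvivalDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return SurvivalDataset(
            X=self.X[:, idx],
            time=self.time,
            event=self.event,
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=self.sample_ids,
            meta=dict(self.meta),
        )

    def subset_samples(self, indices) -> "SurvivalDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return SurvivalDataset(
            X=self.X[idx],
            time=self.time[idx],
            event=self.event[idx],
            feature_ids=self.feature_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            meta=dict(self.meta),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, members)."""

    sets: dict

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str):
        return self.sets[name][1]


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Read a delimited expression matrix (header row + label column).

    ``orientation`` declares the on-disk layout; the result is always
    features x samples.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"empty expression matrix in {path}")
    _check_unique(header.split(sep)[1:], "column labels")  # pandas mangles dups
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    _check_unique(df.index.tolist(), "row labels")
    _check_unique(df.columns.tolist(), "column labels")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-numeric or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if orientation == "samples_in_rows":
        values = values.T
        return ExpressionMatrix(values, df.columns.tolist(), df.index.tolist())
    return ExpressionMatrix(values, df.index.tolist(), df.columns.tolist())


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.feature_ids, columns=expr.sample_ids)
    df.to_csv(path, sep=_sep_for(path))


def read_survival(path) -> SurvivalTable:
    """Read a survival table CSV with columns sample_id, time, event."""
    df = pd.read_csv(path)
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return SurvivalTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
    )


def write_survival(surv: SurvivalTable, path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name <TAB> description <TAB> members..."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description, >=1 member"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def assemble_dataset(expr: ExpressionMatrix, surv: SurvivalTable) -> SurvivalDataset:
    """Intersection-join expression and survival records into a dataset.

    Samples are ordered by their order in the survival table; dropped ids
    are recorded in ``meta['dropped_expr_only']`` / ``meta['dropped_surv_only']``.
    """
    expr_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    keep = [(j, s) for j, s in enumerate(surv.sample_ids) if s in expr_pos]
    if not keep:
        raise ValueError("no samples shared between expression and survival inputs")
    surv_idx = np.array([j for j, _ in keep])
    expr_idx = np.array([expr_pos[s] for _, s in keep])
    kept_ids = [s for _, s in keep]
    meta = {
        "dropped_expr_only": [s for s in expr.sample_ids if s not in set(kept_ids)],
        "dropped_surv_only": [s for s in surv.sample_ids if s not in expr_pos],
    }
    event = surv.event[surv_idx]
    if int(event.sum()) < 2:
        raise ValueError(
            f"only {int(event.sum())} events among the {len(kept_ids)} shared "
            "samples; at least 2 are required"
        )
    return SurvivalDataset(
        X=expr.values[:, expr_idx].T,
        time=surv.time[surv_idx],
        event=event,
        feature_ids=expr.feature_ids,
        sample_ids=kept_ids,
        meta=meta,
    )


def iqr_filter(
    ds: SurvivalDataset,
    keep_fraction: float = 0.2,
    min_iqr: float | None = None,
) -> SurvivalDataset:
    """Drop near-constant features by interquartile range.

    Per feature the IQR of its values across samples is computed with the
    linearly interpolated quantile convention; the ``ceil(keep_fraction * p)``
    features of largest IQR are retained (ties broken by original feature
    order).  ``min_iqr``, if given, instead keeps every feature whose IQR is
    at least the cutoff.  Survival fields are untouched.
    """
    q25, q75 = np.percentile(ds.X, [25, 75], axis=0, method="linear")
    iqr = q75 - q25
    if min_iqr is not None:
        kept = np.flatnonzero(iqr >= min_iqr)
        if kept.size == 0:
            raise ValueError(f"no feature has IQR >= {min_iqr}")
    else:
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        k = math.ceil(keep_fraction * ds.p)
        order = np.argsort(-iqr, kind="stable")  # ties -> original order first
        kept = np.sort(order[:k])
    out = ds.subset_features(kept)
    out.meta["iqr_kept"] = int(kept.size)
    out.meta["iqr_total"] = int(ds.p)
    return out
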