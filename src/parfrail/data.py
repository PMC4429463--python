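"""Clustered right-censored survival data: loading, validation, summaries.

The expected on-disk form is a flat delimited table with columns
``cluster,time,event,<covariate...>`` — one row per subject, times in days,
event coded 1 (cured / event observed) and 0 (right-censored).  A schema
declares each covariate's ordered category labels; the first label is the
reference level used when models dummy-encode the covariate.

Shared-frailty models are only identified within clusters of at least two
subjects, so :func:`filter_singleton_clusters` drops single-subject
clusters and reports what it removed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

RESERVED_COLUMNS = ("cluster", "time", "event")


class SchemaError(ValueError):
    """The table does not match the declared covariate schema."""


class RowValidationError(ValueError):
    """A specific row violates the data contract; the message names it."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up: cluster label, days observed, event flag."""

    cluster_id: str
    time: float
    event: int
    covariates: dict[str, str]

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class ClusteredSurvivalDataset:
    """Validated clustered survival data plus its covariate schema.

    ``frame`` keeps one row per subject with columns cluster/time/event and
    the covariates as pandas Categoricals ordered per the schema.
    """

    frame: pd.DataFrame
    schema: dict[str, list[str]]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return self.frame["cluster"].nunique()

    @property
    def covariates(self) -> list[str]:
        return list(self.schema)

    def cluster_sizes(self) -> pd.Series:
        return self.frame.groupby("cluster", observed=True).size()

    def records(self):
        for _, row in self.frame.iterrows():
            yield SubjectRecord(
                cluster_id=str(row["cluster"]),
                time=float(row["time"]),
                event=int(row["event"]),
                covariates={c: str(row[c]) for c in self.schema},
            )


def load_schema(source) -> dict[str, list[str]]:
    """Read a covariate schema from YAML/JSON text, a path, or a dict."""
    if isinstance(source, dict):
        schema = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        schema = yaml.safe_load(text)
    if schema is None:
        schema = {}
    if not isinstance(schema, dict):
        raise SchemaError("schema must map covariate names to label lists")
    clean: dict[str, list[str]] = {}
    for name, labels in schema.items():
        labels = [str(l) for l in labels]
        if len(labels) < 2:
            raise SchemaError(f"covariate {name!r} needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise SchemaError(f"covariate {name!r} has duplicate labels")
        clean[str(name)] = labels
    return clean


def load_dataset(table, schema) -> ClusteredSurvivalDataset:
    """Load and validate a subject table against a covariate schema.

    ``table`` may be a path, a CSV string, or a DataFrame.  Unknown category
    labels, nonpositive times and events outside {0, 1} are rejected with
    the offending row named.
    """
    schema = load_schema(schema)
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        text = Path(table).read_text() if Path(str(table)).exists() else str(table)
        df = pd.read_csv(io.StringIO(text))
    missing = [c for c in (*RESERVED_COLUMNS, *schema) if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing required columns: {missing}")

    df = df.reset_index(drop=True)
    df["cluster"] = df["cluster"].astype(str)
    time = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[~(time > 0) | time.isna()]
    if len(bad):
        raise RowValidationError(f"row {bad[0]}: time must be a positive number")
    df["time"] = time.astype(float)
    event = pd.to_numeric(df["event"], errors="coerce")
    bad = df.index[~event.isin([0, 1])]
    if len(bad):
        raise RowValidationError(f"row {bad[0]}: event must be 0 or 1")
    df["event"] = event.astype(int)

    for name, labels in schema.items():
        col = df[name].astype(str)
        if col.isna().any() or (col == "nan").any():
            raise RowValidationError(
                f"row {int(df.index[(col == 'nan') | col.isna()][0])}: "
                f"missing value for covariate {name!r}"
            )
        unknown = df.index[~col.isin(labels)]
        if len(unknown):
            raise RowValidationError(
                f"row {unknown[0]}: label {col[unknown[0]]!r} for covariate "
                f"{name!r} is not in the declared schema {labels}"
            )
        df[name] = pd.Categorical(col, categories=labels, ordered=True)

    return ClusteredSurvivalDataset(frame=df[[*RESERVED_COLUMNS, *schema]], schema=schema)


def filter_singleton_clusters(
    ds: ClusteredSurvivalDataset,
) -> tuple[ClusteredSurvivalDataset, dict]:
    """Drop clusters contributing a single subject.

    Returns the filtered dataset plus a report of removed cluster ids and
    counts.  Idempotent and order-preserving.
    """
    sizes = ds.cluster_sizes()
    singles = sizes.index[sizes == 1]
    keep = ds.frame[~ds.frame["cluster"].isin(singles)].reset_index(drop=True)
    if keep.empty:
        raise ValueError("all clusters are singletons; nothing left to analyze")
    report = {
        "removed_clusters": sorted(map(str, singles)),
        "n_removed_clusters": int(len(singles)),
        "n_removed_subjects": int(len(singles)),
        "n_retained_clusters": int(keep["cluster"].nunique()),
        "n_retained_subjects": int(len(keep)),
    }
    return ClusteredSurvivalDataset(frame=keep, schema=ds.schema), report


def _km_median_ci(time: np.ndarray, event: np.ndarray) -> tuple[float, float, float]:
    """Censoring-aware median and 95% CI via the product-limit estimator."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(v) for v in np.asarray(ci).ravel()[:2])
    return med, lo, hi


def describe(ds: ClusteredSurvivalDataset, km_median: bool = True) -> pd.DataFrame:
    """Descriptive summary per covariate category plus an overall row.

    Gives n, events, percent with the event, and the median time with a 95%
    CI.  Medians are Kaplan–Meier medians by default (the times are right
    censored); ``km_median=False`` gives raw sample medians instead, with
    the CI columns left blank.
    """
    if ds.n_subjects == 0:
        raise ValueError("empty dataset")
    rows = []

    def one(covariate: str, category: str, sub: pd.DataFrame) -> dict:
        n, d = len(sub), int(sub["event"].sum())
        pct = round(100.0 * d / n, 2) if n else float("nan")
        if km_median:
            med, lo, hi = _km_median_ci(sub["time"].to_numpy(), sub["event"].to_numpy())
        else:
            med, lo, hi = float(sub["time"].median()), float("nan"), float("nan")
        return {
            "covariate": covariate,
            "category": category,
            "n": n,
            "n_event": d,
            "percent_event": pct,
            "median_days": med,
            "ci_low": lo,
            "ci_high": hi,
            "all_censored": d == 0,
        }

    for name in ds.schema:
        for label in ds.schema[name]:
            sub = ds.frame[ds.frame[name] == label]
            if len(sub):
                rows.append(one(name, label, sub))
    rows.append(one("overall", "all", ds.frame))
    return pd.DataFrame(rows)
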