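"""Cross-sample presence/absence analytics.

Uniqueness is a set property on assigned formulas after blank
subtraction: a formula is unique to a group (a single sample, a site, or
a calendar month) when it occurs in at least one member of that group
and in no sample outside it.  Intensity plays no role — compounds are
counted, not weighed.

Regressions of per-occasion unique-compound counts against composition
metrics are ordinary least squares (statsmodels), reported as slope,
intercept, adjusted R^2 and the two-sided slope p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spectra_io import AssignedSample, SampleMetadata

SEASONS = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
}

GROUPINGS = ("sample", "site", "month")


class ComparisonError(ValueError):
    """Fewer than two samples, or an unknown grouping key."""


class DegenerateRegressionError(ValueError):
    """Too few points or zero variance in the predictor."""


def build_presence_matrix(samples: list[AssignedSample]) -> pd.DataFrame:
    """Boolean formulas-by-samples matrix over the union of assigned
    formulas (rows sorted by Hill string, columns in input order)."""
    if len(samples) < 2:
        raise ComparisonError("presence comparison requires at least 2 samples")
    ids = [s.meta.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ComparisonError("sample ids must be distinct")
    sets = {s.meta.sample_id: {f.hill() for f in s.formulas()} for s in samples}
    rows = sorted(set().union(*sets.values()))
    data = {sid: [f in sets[sid] for f in rows] for sid in ids}
    return pd.DataFrame(data, index=pd.Index(rows, name="formula"))


def _group_of(meta: SampleMetadata, grouping: str) -> str:
    if grouping == "sample":
        return meta.sample_id
    if grouping == "site":
        return meta.site_id
    if grouping == "month":
        if meta.collection_date is None:
            raise ComparisonError(f"{meta.sample_id} has no collection_date for month grouping")
        return f"{meta.collection_date.month:02d}"
    raise ComparisonError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


@dataclass
class UniqueReport:
    """Per-group presence and uniqueness counts.

    ``table`` columns: group, n_formulas (distinct formulas present in the
    group), n_unique (present in no other group), pct_unique.
    """

    grouping: str
    table: pd.DataFrame
    n_total_formulas: int
    n_shared_formulas: int


def unique_compounds(
    matrix: pd.DataFrame,
    grouping: str = "sample",
    metadata: dict[str, SampleMetadata] | None = None,
) -> UniqueReport:
    """Count formulas unique to each group of the presence matrix.

    ``metadata`` maps sample id to :class:`SampleMetadata` and is required
    for the site and month groupings; per-sample uniqueness is the
    degenerate single-member grouping.
    """
    if grouping not in GROUPINGS:
        raise ComparisonError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    if grouping == "sample":
        col_group = {sid: sid for sid in matrix.columns}
    else:
        if metadata is None:
            raise ComparisonError(f"grouping {grouping!r} requires sample metadata")
        col_group = {sid: _group_of(metadata[sid], grouping) for sid in matrix.columns}

    groups = sorted(set(col_group.values()))
    presence = pd.DataFrame({
        g: matrix[[c for c, gg in col_group.items() if gg == g]].any(axis=1)
        for g in groups
    })
    n_groups_present = presence.sum(axis=1)
    rows = []
    for g in groups:
        present = presence[g]
        n_formulas = int(present.sum())
        n_unique = int((present & (n_groups_present == 1)).sum())
        rows.append((g, n_formulas, n_unique,
                     100.0 * n_unique / n_formulas if n_formulas else 0.0))
    table = pd.DataFrame(rows, columns=["group", "n_formulas", "n_unique", "pct_unique"])
    return UniqueReport(
        grouping=grouping, table=table,
        n_total_formulas=int(len(matrix)),
        n_shared_formulas=int((n_groups_present > 1).sum()),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n: int


def regress_unique(unique_counts, metric_values) -> RegressionResult:
    """OLS of a composition metric (y) on unique-compound counts (x)."""
    x = np.asarray(unique_counts, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("unique_counts and metric_values must be equal-length 1-D")
    if len(x) < 3:
        raise DegenerateRegressionError(f"need >= 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("zero variance in unique-compound counts")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        adj_r2=float(fit.rsquared_adj), p_value=float(fit.pvalues[1]),
        n=len(x),
    )


def regression_table(report: UniqueReport, metrics: pd.DataFrame,
                     metric_columns: list[str]) -> pd.DataFrame:
    """Regress each named metric column on per-group unique counts.

    ``metrics`` must carry one row per group in ``report`` (matched on the
    ``group`` column against the metrics' ``sample_id`` for the sample
    grouping, or a ``group`` column otherwise).
    """
    key = "sample_id" if report.grouping == "sample" else "group"
    merged = report.table.merge(metrics, left_on="group", right_on=key)
    rows = []
    for col in metric_columns:
        r = regress_unique(merged["n_unique"], merged[col])
        rows.append((col, r.n, r.adj_r2, r.p_value, r.intercept, r.slope))
    return pd.DataFrame(rows, columns=["variable", "n", "adj_r2", "p", "intercept", "slope"])
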