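"""Cohort descriptive statistics and between-arm inference.

Reproduces the usual trial Table-2 layout: per-arm counts/percentages with a
chi-squared test for categorical variables (Yates continuity correction for
2x2 tables, plain Pearson otherwise) and per-arm mean +/- SD with a
pooled-variance independent-samples t-test for continuous variables.  The
t-test operates on summary statistics, so printed table rows are directly
testable; Welch's correction is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import as_patient_frame

__all__ = ["GroupSummary", "chi2_test", "t_test", "t_test_records", "summarize"]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of a continuous variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def chi2_test(table, continuity_correction: bool = True) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a contingency table.

    For 2x2 tables the Yates continuity correction is applied by default;
    larger tables always use the plain Pearson statistic.  Raises if any
    expected cell count is zero (the test is undefined there), naming the cell.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("cell counts must be >= 0")
    if obs.sum() < 1:
        raise ValueError("grand total must be >= 1")
    expected = stats.contingency.expected_freq(obs)
    zero = np.argwhere(expected == 0)
    if zero.size:
        i, j = zero[0]
        raise ValueError(f"expected count is zero in cell ({i}, {j})")
    correction = continuity_correction and obs.shape == (2, 2)
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


def t_test(summary_a: GroupSummary, summary_b: GroupSummary,
           pooled: bool = True) -> tuple[float, float]:
    """Independent-samples t-test from group summaries (mean, sd, n).

    Pooled-variance Student's t by default; ``pooled=False`` gives Welch's
    unequal-variance test.
    """
    for s in (summary_a, summary_b):
        if s.n < 2:
            raise ValueError("each group needs n >= 2")
        if s.sd <= 0:
            raise ValueError("each group needs sd > 0")
    res = stats.ttest_ind_from_stats(
        summary_a.mean, summary_a.sd, summary_a.n,
        summary_b.mean, summary_b.sd, summary_b.n,
        equal_var=pooled,
    )
    return float(res.statistic), float(res.pvalue)


def t_test_records(x, y, pooled: bool = True) -> tuple[float, float]:
    """Same test computed from raw observations (matches :func:`t_test` on their summaries)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return t_test(GroupSummary(x.size, float(x.mean()), float(x.std(ddof=1))),
                  GroupSummary(y.size, float(y.mean()), float(y.std(ddof=1))),
                  pooled=pooled)


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    vals = series.dropna().unique()
    return set(np.asarray(vals).tolist()) <= {0, 1}


def summarize(records, variables: list[str], by: str = "arm",
              permissive: bool = False) -> pd.DataFrame:
    """Per-arm summary table with between-arm test p-values.

    Continuous variables get n / mean / sd per arm and a pooled t-test;
    categorical (including 0/1 indicators) get per-level count / percent and
    a chi-squared test.  A single-observation arm reports sd as NaN.
    Per-variable n is reported (denominators may differ with missing data).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = as_patient_frame(records)
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")
    arms = list(dict.fromkeys(df[by]))
    rows: list[dict] = []
    for var in variables:
        sub = df[[by, var]].dropna()
        if _is_categorical(sub[var]):
            counts = pd.crosstab(sub[var], sub[by])
            counts = counts.reindex(columns=arms, fill_value=0)
            try:
                _, p = chi2_test(counts.T.to_numpy())
            except ValueError:
                p = np.nan
            for level, row in counts.iterrows():
                out = {"variable": var, "level": level, "p_value": p}
                for a in arms:
                    n_arm = int(counts[a].sum())
                    out[f"{a}_n"] = int(row[a])
                    out[f"{a}_pct"] = 100.0 * row[a] / n_arm if n_arm else np.nan
                rows.append(out)
        else:
            groups = {a: sub.loc[sub[by] == a, var].to_numpy(float) for a in arms}
            out = {"variable": var, "level": None}
            for a, vals in groups.items():
                out[f"{a}_n"] = vals.size
                out[f"{a}_mean"] = vals.mean() if vals.size else np.nan
                out[f"{a}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            try:
                _, p = t_test_records(*(groups[a] for a in arms[:2]))
            except (ValueError, TypeError):
                p = np.nan
            out["p_value"] = p
            rows.append(out)
    return pd.DataFrame(rows)
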