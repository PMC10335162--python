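"""Cohort-level summaries, two-group comparisons, and paired validation.

Comparison rows mirror the usual clinical-table layout (measurement, group
mean +/- SD, p, significance at alpha = 0.05).  The default two-group test
is Welch's t; Student's t and Mann-Whitney are available.  The paired
validation uses a Wilcoxon signed-rank test that is exact (full distribution
of the positive-rank sum, midranks included) for n <= 25 paired differences
and falls back to the normal approximation beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError
from .measures import MEASUREMENT_COLUMNS, MeasurementRecord

__all__ = [
    "ALPHA",
    "ComparisonRow",
    "records_to_frame",
    "summarize",
    "compare_groups",
    "paired_validation",
    "signed_rank_exact_p",
    "comparison_report",
]

ALPHA = 0.05

#: Columns excluded from statistical comparison (identifier / binary flag).
_NON_NUMERIC = ("subject_id", "scleral_show_flag")

_METHODS = ("welch_t", "student_t", "mann_whitney")


@dataclass
class ComparisonRow:
    measurement: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    method: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def records_to_frame(records: Iterable[MeasurementRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [r.to_dict() for r in records]
    if not rows:
        raise ParameterError("no measurement records supplied")
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def summarize(records: Iterable[MeasurementRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-measurement mean, SD (n-1 denominator) and n.

    With a single record the SD is reported as 0 and flagged via ``n = 1``.
    """
    df = records_to_frame(records)
    if len(df) < 1:
        raise ParameterError("summarize requires at least one record")
    cols = [c for c in df.columns if c not in _NON_NUMERIC]
    out = []
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce").dropna().to_numpy(dtype=float)
        n = len(vals)
        out.append(
            {
                "measurement": c,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                "n": n,
            }
        )
    return pd.DataFrame(out).set_index("measurement")


def compare_groups(
    group_a: Iterable[MeasurementRecord] | pd.DataFrame,
    group_b: Iterable[MeasurementRecord] | pd.DataFrame,
    method: str = "welch_t",
    bh_correction: bool = False,
) -> list[ComparisonRow]:
    """Two-sided per-measurement comparison between two cohorts."""
    if method not in _METHODS:
        raise ParameterError(f"method must be one of {_METHODS}, got {method!r}")
    df_a = records_to_frame(group_a)
    df_b = records_to_frame(group_b)
    cols_a = [c for c in df_a.columns if c not in _NON_NUMERIC]
    cols_b = [c for c in df_b.columns if c not in _NON_NUMERIC]
    if set(cols_a) != set(cols_b):
        diff = sorted(set(cols_a) ^ set(cols_b))
        raise SchemaError(f"groups have mismatched measurement columns: {diff}")
    if len(df_a) < 2 or len(df_b) < 2:
        raise ParameterError("each group needs at least 2 records")

    rows: list[ComparisonRow] = []
    for c in cols_a:
        a = pd.to_numeric(df_a[c], errors="coerce").dropna().to_numpy(dtype=float)
        b = pd.to_numeric(df_b[c], errors="coerce").dropna().to_numpy(dtype=float)
        if method == "welch_t":
            res = stats.ttest_ind(a, b, equal_var=False)
        elif method == "student_t":
            res = stats.ttest_ind(a, b, equal_var=True)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            ComparisonRow(
                measurement=c,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                n_a=len(a),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                n_b=len(b),
                method=method,
                statistic=float(res.statistic),
                p_value=float(np.clip(res.pvalue, 0.0, 1.0)),
            )
        )
    if bh_correction:
        ps = np.array([r.p_value for r in rows])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        for r, q in zip(rows, adj):
            r.p_value = float(q)
    return rows


def signed_rank_exact_p(diffs: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value via the full W+ distribution.

    Zero differences are dropped (Wilcoxon convention); ties get midranks.
    The distribution of the positive-rank sum under the symmetric null is
    built by dynamic programming over doubled (integer) midranks, which is
    exact for arbitrary tie patterns; with all differences zero the test is
    vacuous and p = 1 is returned.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    # doubled midranks are integers; W+ support is {0, ..., sum}
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w_obs = int(np.rint(2.0 * ranks[d > 0].sum()))
    mu = total / 2.0
    dev = abs(w_obs - mu)
    idx = np.arange(total + 1)
    extreme = counts[np.abs(idx - mu) >= dev - 1e-9].sum()
    return float(Fraction(int(extreme), 2**n))


def paired_validation(
    method_values: Sequence[float], reference_values: Sequence[float]
) -> dict:
    """Paired agreement between a method and a reference measurement series.

    Returns the mean and SD of the absolute differences plus a two-sided
    Wilcoxon signed-rank p-value on the signed differences (exact for
    n <= 25, normal approximation beyond).
    """
    m = np.asarray(method_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if m.shape != r.shape:
        raise SchemaError(f"length mismatch: {m.shape} vs {r.shape}")
    if m.ndim != 1 or len(m) < 5:
        raise ParameterError("paired_validation needs >= 5 paired values")
    diffs = m - r
    abs_d = np.abs(diffs)
    nonzero = diffs[diffs != 0.0]
    if len(nonzero) == 0:
        p = 1.0
    elif len(nonzero) <= 25:
        p = signed_rank_exact_p(diffs)
    else:
        res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                             method="approx")
        p = float(res.pvalue)
    return {
        "n": len(m),
        "mean_abs_diff": float(abs_d.mean()),
        "sd_abs_diff": float(abs_d.std(ddof=1)) if len(m) > 1 else 0.0,
        "p_value": p,
    }


def comparison_report(
    rows: list[ComparisonRow],
    label_a: str = "A",
    label_b: str = "B",
    format: str = "csv",
) -> str | pd.DataFrame:
    """Render comparison rows as a DataFrame (csv) or a Markdown table."""
    df = pd.DataFrame(
        [
            {
                "measurement": r.measurement,
                f"{label_a}_mean": r.mean_a,
                f"{label_a}_sd": r.sd_a,
                f"{label_b}_mean": r.mean_b,
                f"{label_b}_sd": r.sd_b,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
    if format == "csv":
        return df
    lines = [
        f"| Measurement | {label_a} (mean ± SD) | {label_b} (mean ± SD) | P | |",
        "|---|---|---|---|---|",
    ]
    for r in rows:
        star = "*" if r.significant else ""
        lines.append(
            f"| {r.measurement} | {r.mean_a:.3f} ± {r.sd_a:.3f} "
            f"| {r.mean_b:.3f} ± {r.sd_b:.3f} | {r.p_value:.3g} | {star} |"
        )
    return "\n".join(lines)
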