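"""Group summaries and nonparametric comparison.

Small cohorts make parametric assumptions untenable, so groups are
summarized by median and interquartile range (linear-interpolation
quantiles) and compared with the Mann-Whitney U test under the normal
approximation with midranks and tie-corrected variance. Conventions are
fixed and stamped into every result: U counts wins of the first sample,
no continuity correction, two-sided p. No multiple-testing correction
is applied across metrics; that choice is recorded in the output
metadata of the comparison report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

METRIC_COLUMNS = (
    "max_distance_km",
    "mean_daily_distance_km",
    "pct_time_at_home",
    "trips_per_week",
)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    metric: str
    n: int
    n_excluded: int
    median: float
    iqr_low: float
    iqr_high: float


def summarize_group(values, group: str = "", metric: str = "") -> GroupSummary:
    """Median and IQR of the non-null values; errors if none remain."""
    values = list(values)
    arr = np.asarray(
        [v for v in values if v is not None and not np.isnan(v)], dtype=float
    )
    n_excluded = len(values) - len(arr)
    if len(arr) == 0:
        raise ValueError(f"group {group!r}, metric {metric!r}: no non-null values")
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return GroupSummary(
        group=group, metric=metric, n=len(arr), n_excluded=n_excluded,
        median=float(q50), iqr_low=float(q25), iqr_high=float(q75),
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float          # wins of sample 1 (orientation stamped below)
    z: float
    p_two_sided: float
    n1: int
    n2: int
    tie_correction_applied: bool
    orientation: str = "U counts wins of group 1"
    continuity_correction: bool = False


def mann_whitney(x, y) -> MannWhitneyResult:
    """Mann-Whitney U with midranks and tie-corrected normal z.

    ``U = R1 - n1(n1+1)/2`` from the midrank sum of the first sample;
    ``z = (U - n1 n2 / 2) / sigma_U`` with the tie-corrected variance
    ``sigma_U^2 = n1 n2 / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1)))``.
    Raises if both samples are one constant value (sigma_U = 0).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0

    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    has_ties = bool(np.any(counts > 1))
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u <= 0:
        raise ValueError("degenerate test: all pooled values identical")
    z = (U - n1 * n2 / 2.0) / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(
        U=float(U), z=float(z), p_two_sided=float(min(p, 1.0)),
        n1=n1, n2=n2, tie_correction_applied=has_ties,
    )


def exact_mann_whitney_p(x, y) -> float:
    """Exact two-sided permutation p for the U statistic by full
    enumeration of group-label assignments (oracle; small samples only)."""
    from itertools import combinations

    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mu = n1 * (N - n1) / 2.0
    obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0 - mu)
    hits = total = 0
    for idx in combinations(range(N), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


@dataclass(frozen=True)
class SeverityRow:
    participant_id: str
    severity: float | None
    missing_severity: bool
    metrics: dict


def severity_order(metas, metrics_by_id: dict) -> pd.DataFrame:
    """PD participants ordered by baseline severity (motor + nonmotor
    partial UPDRS, summed), ascending; ties broken by participant id.

    Participants without a baseline score sort last and are flagged
    (``missing_severity``), never silently dropped. The frame carries
    the severity score and the four Lifespace metrics, ready for
    severity-panel rendering.
    """
    rows = []
    for m in metas:
        if m.group != "PD":
            continue
        sev = m.severity_baseline
        met = metrics_by_id.get(m.participant_id)
        row = {
            "participant_id": m.participant_id,
            "severity": sev,
            "missing_severity": sev is None,
        }
        for col in METRIC_COLUMNS:
            row[col] = getattr(met, col, None) if met is not None else None
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    df["_sev_key"] = df["severity"].fillna(np.inf)
    df = df.sort_values(["_sev_key", "participant_id"], kind="stable")
    return df.drop(columns="_sev_key").reset_index(drop=True)


@dataclass
class GroupComparison:
    """Cohort comparison results: per-metric group summaries plus the
    Mann-Whitney test, shaped like a two-group summary table."""

    summaries: list[GroupSummary]
    tests: dict[str, MannWhitneyResult]
    groups: tuple[str, str] = ("PD", "control")
    multiple_testing_correction: str = "none"

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for s in self.summaries:
            rows.setdefault(s.group, {})[s.metric] = (
                f"{s.median:.2f} ({s.iqr_low:.2f}-{s.iqr_high:.2f})"
            )
        test_row = {
            m: f"z={t.z:.2f} P={t.p_two_sided:.2f}" for m, t in self.tests.items()
        }
        df = pd.DataFrame(
            [rows.get(self.groups[0], {}), rows.get(self.groups[1], {}), test_row],
            index=[self.groups[0], self.groups[1], "comparison"],
        )
        return df

    def summary(self) -> str:
        lines = ["Lifespace group comparison (median (IQR); Mann-Whitney z, two-sided P)"]
        lines.append(self.to_frame().to_string())
        lines.append(f"multiple-testing correction: {self.multiple_testing_correction}")
        return "\n".join(lines)


def compare_groups(
    metrics_df: pd.DataFrame,
    groups: tuple[str, str] = ("PD", "control"),
    metric_columns=METRIC_COLUMNS,
) -> GroupComparison:
    """Summarize and test each metric between two groups.

    ``metrics_df`` needs a ``group`` column plus the metric columns;
    null metric values are excluded per group (counted in the summary).
    """
    summaries = []
    tests = {}
    for metric in metric_columns:
        vals = {}
        for g in groups:
            col = metrics_df.loc[metrics_df["group"] == g, metric]
            vals[g] = col.dropna().to_numpy(dtype=float)
            summaries.append(
                summarize_group(col.tolist(), group=g, metric=metric)
            )
        tests[metric] = mann_whitney(vals[groups[0]], vals[groups[1]])
    return GroupComparison(summaries=summaries, tests=tests, groups=groups)
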