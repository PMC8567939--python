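"""Pre/post and between-group comparison battery.

Within-group change is a two-sided paired t-test; between-group
comparisons use Welch's t-test (unequal variances -- the arms differ in
size) or the Mann-Whitney U-test; a chi-squared test is available for
categorical plumbing.  "Degree of change" compares the per-patient
(post - pre) deltas of the two groups with Welch's t-test.  Raw p-values,
no multiplicity correction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_change_test",
    "group_difference_test",
    "change_difference_test",
    "chi_squared_test",
    "build_group_table",
]

METHODS = ("paired-t", "independent-t", "mann-whitney-u", "chi-squared")


@dataclasses.dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    degenerate: bool = False  # zero-variance input; p/statistic not meaningful

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _arr(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def paired_change_test(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on per-patient (post - pre) differences.

    Identical pre/post vectors give statistic 0 and p = 1; non-zero but
    constant differences are flagged degenerate (zero variance) instead
    of reporting p = 0.
    """
    pre, post = _arr(pre), _arr(post)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal lengths)")
    if pre.size < 2:
        raise ValueError("need at least two pairs")
    d = post - pre
    if np.allclose(d, 0.0):
        return TestResult("paired-t", 0.0, 1.0, (pre.size,))
    if np.std(d, ddof=1) == 0.0:
        return TestResult("paired-t", np.inf, np.nan, (pre.size,), degenerate=True)
    t, p = sps.ttest_rel(post, pre)
    return TestResult("paired-t", float(t), float(p), (pre.size,))


def group_difference_test(
    a: Sequence[float], b: Sequence[float], method: str = "independent-t"
) -> TestResult:
    """Two-sided between-group test by the named method.

    ``independent-t`` is Welch's unequal-variance form; ``mann-whitney-u``
    uses the two-sided exact/normal rule scipy selects.
    """
    a, b = _arr(a), _arr(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    n = (a.size, b.size)
    if method == "independent-t":
        if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
            if np.mean(a) == np.mean(b):
                return TestResult("independent-t", 0.0, 1.0, n)
            return TestResult("independent-t", np.inf, np.nan, n, degenerate=True)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return TestResult("independent-t", float(t), float(p), n)
    if method == "mann-whitney-u":
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("mann-whitney-u", float(u), float(p), n)
    raise ValueError(f"unknown method {method!r}")


def change_difference_test(
    pre_a: Sequence[float],
    post_a: Sequence[float],
    pre_b: Sequence[float],
    post_b: Sequence[float],
) -> TestResult:
    """Degree-of-change test: Welch t between the groups' paired deltas."""
    pre_a, post_a, pre_b, post_b = map(_arr, (pre_a, post_a, pre_b, post_b))
    if pre_a.size != post_a.size or pre_b.size != post_b.size:
        raise ValueError("periods must be paired within each group")
    if pre_a.size < 2 or pre_b.size < 2:
        raise ValueError("each group needs at least two patients")
    return group_difference_test(post_a - pre_a, post_b - pre_b, "independent-t")


def chi_squared_test(table: np.ndarray) -> TestResult:
    """Chi-squared test of independence on a contingency table."""
    table = np.asarray(table, dtype=float)
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(
        "chi-squared", float(res.statistic), float(res.pvalue),
        tuple(int(x) for x in table.sum(axis=1)),
    )


def build_group_table(
    values: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    groups: Sequence[str] = ("RYGB", "OAGB"),
) -> pd.DataFrame:
    """Assemble the summary-table layout: group x period means +/- sd and
    the three p-value columns.

    ``values`` is tidy with columns ``patient_id, group, period, metric,
    value`` and one row per patient-period-metric; every patient must
    appear in both periods for every metric.  Output rows are metrics;
    columns are ``<group>_pre/_post`` as "mean +/- sd", within-group
    paired p per group, and (when both groups are present) between-group
    p for each period plus the degree-of-change p.
    """
    required = {"patient_id", "group", "period", "metric", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    metrics = list(metrics) if metrics is not None else list(values["metric"].unique())
    groups = [g for g in groups if g in set(values["group"])]
    rows = []
    for metric in metrics:
        sub = values[values["metric"] == metric]
        row: dict[str, object] = {"metric": metric}
        per_group: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for g in groups:
            gsub = sub[sub["group"] == g]
            pre = gsub[gsub["period"] == "pre"].set_index("patient_id")["value"]
            post = gsub[gsub["period"] == "post"].set_index("patient_id")["value"]
            missing = set(pre.index) ^ set(post.index)
            if missing:
                raise ValueError(
                    f"patient(s) {sorted(missing)} missing a period for {metric!r}"
                )
            pre = pre.sort_index()
            post = post.reindex(pre.index)
            per_group[g] = (pre.to_numpy(), post.to_numpy())
            row[f"{g}_pre"] = f"{pre.mean():.3g} ± {pre.std(ddof=1):.3g}"
            row[f"{g}_post"] = f"{post.mean():.3g} ± {post.std(ddof=1):.3g}"
            row[f"{g}_p_prepost"] = paired_change_test(pre, post).p_value
        if len(groups) == 2:
            (pre_a, post_a), (pre_b, post_b) = (per_group[g] for g in groups)
            row["p_preOP"] = group_difference_test(pre_a, pre_b).p_value
            row["p_postOP"] = group_difference_test(post_a, post_b).p_value
            row["p_change"] = change_difference_test(
                pre_a, post_a, pre_b, post_b
            ).p_value
        else:
            row["p_preOP"] = row["p_postOP"] = row["p_change"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
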