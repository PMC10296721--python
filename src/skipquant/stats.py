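"""Case-control statistics on the cohort table.

Reproduces the analysis layer of the splicing study: per-group prevalence of
any skip-junction evidence, a two-group Mann–Whitney rank-sum comparison of
the per-sample skipped-isoform percentage, the same comparison stratified by
sex, and a one-way ANOVA of the percentage across APOE genotypes.

Conventions
-----------
* All tests are two-sided.
* Samples with an NA ratio (no junction reads) are excluded from rank-based
  tests and ANOVA but kept in prevalence denominators.
* Mann–Whitney uses midranks for ties; the p-value is exact (full
  enumeration) when the pooled sample is small (``n_a + n_b <= 12``) and
  tie-free, otherwise the normal approximation with tie-corrected variance
  and continuity correction.
* One-way ANOVA with zero within-group variance but non-zero between-group
  variance reports F = +inf and p = 0 (perfectly separated degenerate case);
  with both variances zero the p-value is NA.
* No multiple-testing correction is applied across panels, matching
  per-panel reporting; a Bonferroni column is emitted for transparency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "prevalence",
    "mann_whitney_u",
    "oneway_anova",
    "stratified_compare",
    "cohort_report",
    "write_stats_report",
]

_SIDEDNESS = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass(frozen=True)
class GroupComparison:
    """One statistical contrast (one panel row of the cohort analysis)."""

    contrast: str
    group_sizes: tuple[int, ...]
    statistic_name: str  # 'prevalence_diff' | 'mann_whitney_U' | 'anova_F'
    statistic: float
    p_value: float  # NaN == not computed / not defined
    sidedness: str = "two_sided"
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 0")


def prevalence(table: pd.DataFrame, group: str, group_col: str = "group") -> float:
    """Percent of samples in ``group`` with any skip-junction evidence.

    NA-ratio samples count in the denominator (they had reads examined but no
    junction evidence, hence no detected splicing).
    """
    sub = table[table[group_col] == group]
    if len(sub) == 0:
        warnings.warn(f"group {group!r} is empty; prevalence undefined")
        return math.nan
    return 100.0 * float(sub["has_splicing"].astype(bool).sum()) / len(sub)


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def mann_whitney_u(
    values_a: Iterable[float],
    values_b: Iterable[float],
    sidedness: str = "two_sided",
    *,
    contrast: str = "A_vs_B",
    method: str = "auto",
) -> GroupComparison:
    """Mann–Whitney rank-sum comparison of two groups (NA values dropped).

    ``method='auto'`` uses exact enumeration for tie-free pooled samples of
    at most 12 values, else the tie-corrected normal approximation with
    continuity correction.  The reported U is the statistic of the first
    group; U_A + U_B = n_a * n_b always holds.
    """
    a = _clean(values_a)
    b = _clean(values_b)
    for name, arr in (("first", a), ("second", b)):
        if arr.size == 0:
            raise ValueError(f"{name} group of contrast {contrast!r} has no non-NA values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every observation tied: no rank information, U at its null mean
        return GroupComparison(
            contrast, (a.size, b.size), "mann_whitney_U",
            a.size * b.size / 2.0, 1.0, sidedness, note="all values tied",
        )
    if method == "auto":
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=_SIDEDNESS[sidedness], method=method, use_continuity=True
    )
    return GroupComparison(
        contrast, (a.size, b.size), "mann_whitney_U",
        float(res.statistic), float(res.pvalue), sidedness, note=method,
    )


def oneway_anova(
    values_by_level: Mapping[str, Iterable[float]] | Sequence[Iterable[float]],
    *,
    contrast: str = "anova",
) -> GroupComparison:
    """One-way fixed-effects ANOVA across the levels (NA values dropped).

    F = MS_between / MS_within with the standard degrees of freedom; p from
    the upper tail of the F distribution.  Degenerate conventions: zero
    within-group variance with non-zero between-group variance gives
    F = +inf, p = 0; both zero gives p = NA.
    """
    if isinstance(values_by_level, Mapping):
        groups = {str(k): _clean(v) for k, v in values_by_level.items()}
    else:
        groups = {str(i): _clean(v) for i, v in enumerate(values_by_level)}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    sizes = tuple(v.size for v in groups.values())
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two levels with data")
    if all(n < 2 for n in sizes):
        raise ValueError("ANOVA requires at least one level with >= 2 values")
    k = len(groups)
    n = sum(sizes)
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = k - 1
    df_within = n - k
    if df_within <= 0:
        raise ValueError("ANOVA requires residual degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            return GroupComparison(
                contrast, sizes, "anova_F", math.nan, math.nan,
                note="no variance anywhere",
            )
        return GroupComparison(
            contrast, sizes, "anova_F", math.inf, 0.0,
            note="zero within-group variance",
        )
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return GroupComparison(contrast, sizes, "anova_F", float(f), p)


def stratified_compare(
    table: pd.DataFrame,
    stratum_column: str,
    *,
    group_col: str = "group",
    value_col: str = "pct_skipped",
    groups: Optional[tuple[str, str]] = None,
    min_per_arm: int = 3,
) -> list[GroupComparison]:
    """Mann–Whitney per stratum level (e.g. the female / male sub-cohorts).

    Strata with fewer than ``min_per_arm`` non-NA values in either arm are
    reported as skipped entries (p = NA) rather than silently dropped.
    """
    if stratum_column not in table.columns:
        raise ValueError(f"no column {stratum_column!r} in table")
    if groups is None:
        labels = sorted(table[group_col].astype(str).unique())
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, found {labels}")
        groups = (labels[0], labels[1])
    out: list[GroupComparison] = []
    for level in sorted(table[stratum_column].astype(str).unique()):
        sub = table[table[stratum_column].astype(str) == level]
        a = _clean(sub.loc[sub[group_col] == groups[0], value_col])
        b = _clean(sub.loc[sub[group_col] == groups[1], value_col])
        label = f"{groups[0]}_vs_{groups[1]}[{stratum_column}={level}]"
        if a.size < min_per_arm or b.size < min_per_arm:
            out.append(
                GroupComparison(
                    label, (a.size, b.size), "mann_whitney_U", math.nan, math.nan,
                    note=f"skipped: fewer than {min_per_arm} non-NA values per arm",
                )
            )
            continue
        out.append(replace(mann_whitney_u(a, b, contrast=label), contrast=label))
    return out


def cohort_report(
    table: pd.DataFrame,
    *,
    group_col: str = "group",
    case_group: str = "AD",
    control_group: str = "NCI",
    sex_col: str = "sex",
    apoe_col: str = "apoe",
    value_col: str = "pct_skipped",
) -> pd.DataFrame:
    """The full panel set: prevalences, case-vs-control rank-sum, sex strata,
    APOE ANOVA — one row per comparison, plus a Bonferroni column.

    Row order of the input table never affects any reported statistic.
    """
    rows: list[GroupComparison] = []
    prev = {
        g: prevalence(table, g, group_col) for g in (case_group, control_group)
    }
    n_case = int((table[group_col] == case_group).sum())
    n_ctrl = int((table[group_col] == control_group).sum())
    rows.append(
        GroupComparison(
            f"prevalence[{case_group}]", (n_case,), "prevalence_pct",
            prev[case_group], math.nan, note="percent of samples with splicing",
        )
    )
    rows.append(
        GroupComparison(
            f"prevalence[{control_group}]", (n_ctrl,), "prevalence_pct",
            prev[control_group], math.nan, note="percent of samples with splicing",
        )
    )
    case_vals = table.loc[table[group_col] == case_group, value_col]
    ctrl_vals = table.loc[table[group_col] == control_group, value_col]
    rows.append(
        mann_whitney_u(
            case_vals, ctrl_vals, contrast=f"{case_group}_vs_{control_group}"
        )
    )
    rows.extend(
        stratified_compare(
            table, sex_col, group_col=group_col,
            groups=(case_group, control_group), value_col=value_col,
        )
    )
    by_apoe = {
        str(lvl): _clean(table.loc[table[apoe_col].astype(str) == str(lvl), value_col])
        for lvl in sorted(table[apoe_col].astype(str).unique())
    }
    by_apoe = {k: v for k, v in by_apoe.items() if v.size > 0}
    if len(by_apoe) >= 2 and any(v.size >= 2 for v in by_apoe.values()):
        rows.append(oneway_anova(by_apoe, contrast=f"{value_col}_by_{apoe_col}"))
    else:
        rows.append(
            GroupComparison(
                f"{value_col}_by_{apoe_col}",
                tuple(v.size for v in by_apoe.values()),
                "anova_F", math.nan, math.nan, note="skipped: too few levels",
            )
        )
    df = pd.DataFrame(
        {
            "contrast": [r.contrast for r in rows],
            "statistic_name": [r.statistic_name for r in rows],
            "group_sizes": ["/".join(map(str, r.group_sizes)) for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "sidedness": [r.sidedness for r in rows],
            "note": [r.note for r in rows],
        }
    )
    n_tests = int(df["p_value"].notna().sum())
    df["p_bonferroni"] = (df["p_value"] * n_tests).clip(upper=1.0)
    return df


def write_stats_report(
    report: pd.DataFrame, tsv_path: str | Path, text_path: Optional[str | Path] = None
) -> None:
    """Write the comparison table as TSV and, optionally, a prose summary."""
    report.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    if text_path is None:
        return
    lines = ["Cohort splicing statistics", "=" * 26, ""]
    for _, r in report.iterrows():
        stat = r["statistic"]
        stat_s = "NA" if pd.isna(stat) else f"{stat:.4g}"
        p = r["p_value"]
        p_s = "NA" if pd.isna(p) else f"{p:.4g}"
        lines.append(
            f"{r['contrast']}: {r['statistic_name']}={stat_s}, p={p_s}"
            + (f" ({r['note']})" if r["note"] else "")
        )
    with open(text_path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
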