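"""Prevalence, Mann-Whitney, one-way ANOVA and stratified contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from skipquant.stats import (
    cohort_report,
    mann_whitney_u,
    oneway_anova,
    prevalence,
    stratified_compare,
    write_stats_report,
)


def brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        gt = sum(1 for x in xs for y in ys if x > y)
        eq = sum(1 for x in xs for y in ys if x == y)
        return gt + 0.5 * eq

    u_obs = u_stat(range(n_a))
    mean_u = n_a * (len(pooled) - n_a) / 2
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_small_sample_exact_p_matches_enumeration(self):
        res = mann_whitney_u([1, 2], [3, 4])
        u_brute, p_brute = brute_force_mw_p([1, 2], [3, 4])
        assert res.statistic == u_brute == 0.0
        assert res.p_value == pytest.approx(p_brute) == pytest.approx(1 / 3)
        assert res.note == "exact"

    @pytest.mark.parametrize(
        "a,b",
        [([1, 5, 7], [2, 3, 9]), ([10, 11], [1, 2, 3, 12]), ([4], [1, 2, 3])],
    )
    def test_exact_p_on_more_tie_free_samples(self, a, b):
        res = mann_whitney_u(a, b)
        u_brute, p_brute = brute_force_mw_p(a, b)
        assert res.statistic == u_brute
        assert res.p_value == pytest.approx(p_brute)

    def test_fully_tied_groups(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res.statistic == 4.5
        assert res.p_value == 1.0

    def test_complementary_u_statistics(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=25)
        u_ab = mann_whitney_u(a, b).statistic
        u_ba = mann_whitney_u(b, a).statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_na_dropped_and_empty_group_errors(self):
        res = mann_whitney_u([1.0, math.nan, 2.0], [3.0, 4.0])
        assert res.group_sizes == (2, 2)
        with pytest.raises(ValueError, match="second"):
            mann_whitney_u([1.0], [math.nan])

    def test_power_under_shifted_beta_alternative(self):
        # generating effect comparable to the case-control splicing contrast
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = np.where(rng.random(100) < 0.15, 0.0, rng.beta(2, 8, 100))
            b = np.where(rng.random(100) < 0.52, 0.0, rng.beta(1.5, 12, 100))
            if mann_whitney_u(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep >= 0.95


class TestOnewayAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = oneway_anova([[1, 2], [1, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_separated_degenerate_groups(self):
        res = oneway_anova([[0, 0], [1, 1]])
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_no_variance_anywhere_gives_na(self):
        res = oneway_anova([[2, 2], [2, 2]])
        assert math.isnan(res.p_value)

    def test_three_level_closed_form(self):
        # hand computation: SS_b = 6 (df 2), SS_w = 6 (df 6) -> F = 3/1 = 3
        res = oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0)
        ref = sps.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_two_level_anova_equals_squared_t(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b = rng.normal(size=12), rng.normal(1.0, 2.0, size=9)
            res = oneway_anova({"a": a, "b": b})
            t = sps.ttest_ind(a, b, equal_var=True)
            assert res.statistic == pytest.approx(t.statistic**2, abs=1e-10)
            assert res.p_value == pytest.approx(t.pvalue, abs=1e-10)

    def test_requires_two_levels(self):
        with pytest.raises(ValueError, match="two levels"):
            oneway_anova([[1, 2, 3]])


def make_table(rng, n_ad=30, n_nci=30, effect=True):
    rows = []
    for group, n in (("AD", n_ad), ("NCI", n_nci)):
        for i in range(n):
            if group == "AD" and effect:
                pct = 0.0 if rng.random() < 0.15 else 100 * rng.beta(2, 8)
            else:
                pct = 0.0 if rng.random() < 0.52 else 100 * rng.beta(1.5, 12)
            rows.append(
                {
                    "sample_id": f"{group}{i}",
                    "group": group,
                    "sex": "F" if rng.random() < 0.6 else "M",
                    "apoe": rng.choice(["23", "33", "34"]),
                    "pct_skipped": pct,
                    "has_splicing": pct > 0,
                }
            )
    return pd.DataFrame(rows)


class TestPrevalence:
    def test_simple_fractions(self):
        df = pd.DataFrame(
            {
                "group": ["AD"] * 4 + ["NCI"] * 5,
                "has_splicing": [True, True, True, False] + [False] * 5,
            }
        )
        assert prevalence(df, "AD") == 75.0
        assert prevalence(df, "NCI") == 0.0

    def test_empty_group_warns_and_returns_nan(self):
        df = pd.DataFrame({"group": ["AD"], "has_splicing": [True]})
        with pytest.warns(UserWarning):
            assert math.isnan(prevalence(df, "NCI"))


class TestStratifiedAndReport:
    def test_one_comparison_per_stratum_level(self):
        table = make_table(np.random.default_rng(1))
        out = stratified_compare(table, "sex", groups=("AD", "NCI"))
        assert len(out) == 2
        assert {c.contrast for c in out} == {
            "AD_vs_NCI[sex=F]", "AD_vs_NCI[sex=M]"
        }

    def test_small_stratum_reported_as_skipped(self):
        table = make_table(np.random.default_rng(2), n_ad=4, n_nci=4)
        table.loc[table.index[:7], "sex"] = "F"
        table.loc[table.index[7:], "sex"] = "M"
        out = stratified_compare(table, "sex", groups=("AD", "NCI"))
        skipped = [c for c in out if c.note.startswith("skipped")]
        assert skipped and all(math.isnan(c.p_value) for c in skipped)

    def test_report_rows_and_row_order_invariance(self):
        rng = np.random.default_rng(3)
        table = make_table(rng)
        rep1 = cohort_report(table)
        shuffled = table.sample(frac=1.0, random_state=11).reset_index(drop=True)
        rep2 = cohort_report(shuffled)
        assert list(rep1["contrast"]) == list(rep2["contrast"])
        for col in ("statistic", "p_value"):
            a = rep1[col].to_numpy(dtype=float)
            b = rep2[col].to_numpy(dtype=float)
            assert np.allclose(a, b, equal_nan=True)
        assert {"prevalence[AD]", "prevalence[NCI]", "AD_vs_NCI"} <= set(rep1["contrast"])
        assert (rep1["p_bonferroni"].dropna() <= 1.0).all()

    def test_report_written_as_tsv_and_text(self, tmp_path):
        table = make_table(np.random.default_rng(4))
        rep = cohort_report(table)
        write_stats_report(rep, tmp_path / "stats.tsv", tmp_path / "stats.txt")
        back = pd.read_csv(tmp_path / "stats.tsv", sep="\t")
        assert len(back) == len(rep)
        assert "AD_vs_NCI" in (tmp_path / "stats.txt").read_text()
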