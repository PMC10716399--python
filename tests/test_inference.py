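"""Gated group statistics: routing, oracles, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from vismotor import inference
from vismotor.inference import (
    compare_groups,
    consumption_tertile,
    mixed_anova,
    normality_gate,
    paired_compare,
    subgroup_analyses,
)


def two_group_table(a, b, order=("NOTV", "TV")):
    return pd.DataFrame(
        {
            "group": [order[0]] * len(a) + [order[1]] * len(b),
            "value": list(a) + list(b),
        }
    )


class TestNormalityGate:
    def test_normal_draws_mostly_parametric(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng([1, rep])
            decision, _ = normality_gate(
                {"a": rng.normal(size=30), "b": rng.normal(size=30)}
            )
            hits += decision == "parametric"
        assert hits >= 90

    def test_cauchy_draws_mostly_nonparametric(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng([2, rep])
            decision, _ = normality_gate({"a": rng.standard_cauchy(size=30)})
            hits += decision == "nonparametric"
        assert hits >= 90

    def test_constant_values_flagged(self):
        decision, log = normality_gate({"a": np.ones(10)})
        assert decision == "nonparametric"
        assert "degenerate" in log["per_group"]["a"]["warning"]

    def test_tiny_group_inconclusive(self):
        decision, log = normality_gate({"a": np.array([1.0, 2.0])})
        assert decision == "nonparametric"
        assert "inconclusive" in log["per_group"]["a"]["warning"]


class TestCompareGroups:
    def test_identical_groups_null(self):
        t = two_group_table([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        res = compare_groups(t, "value")
        assert res.extra["mean_difference"] == 0
        assert res.effect_size == 0
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_fixture(self):
        # {1..5} vs {3..7}: mean diff -2, pooled SD sqrt(2.5), d = -1.2649
        t = two_group_table([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        res = compare_groups(t, "value")
        assert res.extra["mean_difference"] == pytest.approx(-2.0)
        assert res.effect_size == pytest.approx(-2 / math.sqrt(2.5), abs=1e-4)
        assert res.test_name in ("student_t", "welch_t")
        assert "shapiro_wilk" == res.assumptions_log["gate"]
        assert "levene" in res.assumptions_log

    def test_d_sign_flips_with_group_order(self):
        t = two_group_table([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        r1 = compare_groups(t, "value", order=("NOTV", "TV"))
        t2 = two_group_table([3, 4, 5, 6, 7], [1, 2, 3, 4, 5])
        r2 = compare_groups(t2, "value", order=("NOTV", "TV"))
        assert r1.effect_size == pytest.approx(-r2.effect_size)

    def test_mann_whitney_monotone_invariance(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.standard_cauchy(size=25))  # wildly non-normal, positive
        b = np.exp(rng.standard_cauchy(size=25)) * 2
        t1 = two_group_table(a, b)
        t2 = two_group_table(a**3, b**3)  # strictly monotone transform
        r1 = compare_groups(t1, "value")
        r2 = compare_groups(t2, "value")
        assert r1.test_name == r2.test_name == "mann_whitney_u"
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_descriptive_ci_uses_z_formula(self):
        vals = np.arange(1, 11, dtype=float)
        lo, hi = inference.descriptive_ci(vals)
        half = 1.959963984540054 * vals.std(ddof=1) / math.sqrt(10)
        assert (lo, hi) == pytest.approx((vals.mean() - half, vals.mean() + half))


class TestPairedCompare:
    def test_no_change_is_null(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(pre, pre)
        assert res.p_value == 1.0
        assert res.extra["mean_change"] == 0.0

    def test_detects_location_shift(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=30)
        res = paired_compare(pre, pre + 1.0)
        assert res.p_value < 0.001
        assert res.extra["mean_change"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        # differences {1,-1,2,3,0,2}: mean 7/6, sd sqrt(13/6), t = 1.9415
        pre = np.zeros(6)
        post = np.array([1.0, -1.0, 2.0, 3.0, 0.0, 2.0])
        res = paired_compare(pre, post)
        assert res.test_name == "paired_t"
        assert res.df == 5
        assert res.statistic == pytest.approx(1.9415, abs=2e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            paired_compare(np.ones(3), np.ones(4))


def _split_plot_oracle(wide, groups):
    """Hand-rolled balanced two-way mixed ANOVA decomposition.

    ``wide``: (subjects x time) matrix; ``groups``: group label per subject.
    Returns (F_group, F_time, F_interaction) from the classical sums of
    squares of a split-plot design.
    """
    labels = np.unique(groups)
    a, t = len(labels), wide.shape[1]
    s = wide.shape[0] // a
    grand = wide.mean()
    subj_means = wide.mean(axis=1)
    group_means = np.array([wide[groups == g].mean() for g in labels])
    time_means = wide.mean(axis=0)
    cell_means = np.array([wide[groups == g].mean(axis=0) for g in labels])

    ss_group = s * t * ((group_means - grand) ** 2).sum()
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = a * s * ((time_means - grand) ** 2).sum()
    ss_int = s * (
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ).sum()
    ss_total = ((wide - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_time - ss_int

    ms_group = ss_group / (a - 1)
    ms_subj = ss_subj_within / (a * (s - 1))
    ms_time = ss_time / (t - 1)
    ms_int = ss_int / ((a - 1) * (t - 1))
    ms_err = ss_err / (a * (s - 1) * (t - 1))
    return ms_group / ms_subj, ms_time / ms_err, ms_int / ms_err


class TestMixedAnova:
    def long_table(self, wide, groups):
        rows = []
        for i in range(wide.shape[0]):
            for d in range(wide.shape[1]):
                rows.append(
                    {"subject_id": f"S{i:02d}", "group": groups[i],
                     "day": d + 1, "value": wide[i, d]}
                )
        return pd.DataFrame(rows)

    def test_matches_split_plot_oracle(self):
        rng = np.random.default_rng(6)
        groups = np.array(["NOTV"] * 8 + ["TV"] * 8)
        wide = (
            rng.normal(size=(16, 5))
            + 0.4 * np.arange(5)
            + 0.5 * (groups == "TV")[:, None]
        )
        res = mixed_anova(self.long_table(wide, groups), dv="value")
        f_group, f_time, f_int = _split_plot_oracle(wide, groups)
        assert res["between"].statistic == pytest.approx(f_group, rel=1e-6)
        assert res["within"].statistic == pytest.approx(f_time, rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(f_int, rel=1e-6)

    def test_gg_epsilon_bounds_and_noop(self):
        rng = np.random.default_rng(7)
        groups = np.array(["NOTV"] * 10 + ["TV"] * 10)
        wide = rng.normal(size=(20, 5))  # exchangeable errors: sphericity holds
        res = mixed_anova(self.long_table(wide, groups), dv="value")
        eps = res["within"].assumptions_log["greenhouse_geisser_eps"]
        assert 1 / 4 <= eps <= 1.0
        df1, df2 = res["within"].df
        if res["within"].assumptions_log["sphericity"]:
            assert (df1, df2) == (4.0, 72.0)  # uncorrected dfs

    def test_null_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            rng = np.random.default_rng([8, rep])
            groups = np.array(["NOTV"] * 8 + ["TV"] * 8)
            wide = rng.normal(size=(16, 5))
            res = mixed_anova(self.long_table(wide, groups), dv="value")
            rejections += res["between"].p_value < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10


class TestSubgroups:
    def make_table(self, rng, n=72):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": ["TV", "NOTV"] * (n // 2),
                "age": rng.integers(18, 31, size=n),
                "gender": rng.choice(["f", "m"], size=n),
                "consumption_h_week": rng.lognormal(math.log(18), 0.5, size=n),
                "content_group": [
                    rng.choice(["Relax", "Mixed", "Thrill"]) if i % 2 == 0 else ""
                    for i in range(n)
                ],
                "mle": rng.normal(1.16, 0.1, size=n),
            }
        )

    def test_null_age_correlation_small(self):
        # SD(r) ~ 1/sqrt(71) ~ 0.12 at n=72, so P(|r| < 0.2) ~ 0.91;
        # the bound allows two binomial SDs below that expectation
        small = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng([9, rep])
            out = subgroup_analyses(self.make_table(rng))
            small += abs(out["age_corr_mle"].statistic) < 0.2
        assert small >= 85

    def test_consumption_null_anova_not_extreme(self):
        rng = np.random.default_rng(10)
        out = subgroup_analyses(self.make_table(rng))
        assert "consumption_anova_mle" in out
        assert 0 <= out["consumption_anova_mle"].p_value <= 1

    @pytest.mark.parametrize(
        "hours, bin_", [(0, "Low"), (14.9, "Low"), (15, "Average"), (29.9, "Average"), (30, "High")]
    )
    def test_tertile_boundaries(self, hours, bin_):
        assert consumption_tertile(hours) == bin_
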