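"""Mixed-design ANOVA, change-score regressions and biomarker calls."""

import numpy as np
import pandas as pd
import pytest

import depmark as dm
from depmark.biomarkers import call_level, classify_trait


def brute_force_mixed_anova(values: pd.DataFrame, groups: pd.Series) -> dict:
    """Independent sums-of-squares oracle using explicit mean decompositions."""
    y = values.to_numpy(float)
    g = groups.to_numpy()
    n, t = y.shape
    grand = y.mean()
    labels = sorted(set(g))
    out = {}
    subj_mean = y.mean(axis=1)
    out["between"] = t * ((subj_mean - grand) ** 2).sum()
    out["group"] = t * sum(
        (g == lab).sum() * (y[g == lab].mean() - grand) ** 2 for lab in labels
    )
    out["subj"] = out["between"] - out["group"]
    out["within"] = ((y - subj_mean[:, None]) ** 2).sum()
    vhat = sum((g == lab).sum() * (y[g == lab].mean(axis=0) - y[g == lab].mean())
               for lab in labels) / n
    out["visit"] = n * (vhat ** 2).sum()
    out["inter"] = sum(
        (g == lab).sum()
        * ((y[g == lab].mean(axis=0) - y[g == lab].mean() - vhat) ** 2).sum()
        for lab in labels
    )
    out["error"] = out["within"] - out["visit"] - out["inter"]
    out["total"] = ((y - grand) ** 2).sum()
    return out


def small_design(seed=0, n_per_group=4, n_visits=3, shift=0.0):
    rng = np.random.default_rng(seed)
    subjects = [f"s{i}" for i in range(2 * n_per_group)]
    groups = pd.Series(["a"] * n_per_group + ["b"] * n_per_group, index=subjects)
    y = rng.normal(size=(2 * n_per_group, n_visits))
    y[n_per_group:] += shift
    return pd.DataFrame(y, index=subjects), groups


class TestRmAnova:
    def test_all_identical_values_degenerate_convention(self):
        values = pd.DataFrame(np.ones((6, 3)), index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
        res = dm.rm_anova(values, groups)
        for eff in ("group", "visit", "group_x_visit"):
            assert res.effect(eff)["F"] == 0.0
            assert res.effect(eff)["p"] == 1.0

    def test_eight_value_hand_dataset_matches_oracle(self):
        values = pd.DataFrame([[1, 2], [2, 3], [3, 4], [4, 5]],
                              index=["s1", "s2", "s3", "s4"], dtype=float)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=values.index)
        res = dm.rm_anova(values, groups)
        ss = brute_force_mixed_anova(values, groups)
        assert res.effect("group")["ss"] == pytest.approx(ss["group"])
        assert res.effect("group")["F"] == pytest.approx(
            (ss["group"] / 1) / (ss["subj"] / 2))
        assert res.effect("visit")["ss"] == pytest.approx(ss["visit"])

    def test_sums_of_squares_decomposition_is_exact(self):
        for seed in range(5):
            values, groups = small_design(seed, n_per_group=5, n_visits=4,
                                          shift=0.7)
            res = dm.rm_anova(values, groups)
            tab = res.table
            total = tab["ss"].sum()
            grand = values.to_numpy().mean()
            assert total == pytest.approx(
                ((values.to_numpy() - grand) ** 2).sum(), abs=1e-9)
            ss = brute_force_mixed_anova(values, groups)
            assert tab.loc["group", "ss"] == pytest.approx(ss["group"], abs=1e-9)
            assert tab.loc["visit", "ss"] == pytest.approx(ss["visit"], abs=1e-9)
            assert tab.loc["group_x_visit", "ss"] == pytest.approx(ss["inter"],
                                                                   abs=1e-9)
            assert tab.loc["error_within", "ss"] == pytest.approx(ss["error"],
                                                                  abs=1e-9)

    def test_agrees_with_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        values, groups = small_design(3, n_per_group=6, n_visits=4, shift=0.5)
        res = dm.rm_anova(values, groups)
        long = values.reset_index(names="subject").melt(
            id_vars="subject", var_name="visit", value_name="y")
        long["group"] = long["subject"].map(groups)
        pg = pingouin.mixed_anova(long, dv="y", within="visit",
                                  subject="subject", between="group").set_index("Source")
        assert res.effect("group")["F"] == pytest.approx(
            pg.loc["group", "F"], rel=1e-6)
        assert res.effect("visit")["F"] == pytest.approx(
            pg.loc["visit", "F"], rel=1e-6)
        assert res.effect("group_x_visit")["F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6)
        assert res.effect("group")["partial_eta2"] == pytest.approx(
            pg.loc["group", "np2"], rel=1e-6)

    def test_two_visit_f_equals_squared_paired_t(self):
        from scipy import stats
        values, groups = small_design(4, n_per_group=5, n_visits=2)
        res = dm.rm_anova(values, groups)
        diff = values.iloc[:, 1] - values.iloc[:, 0]
        # paired t on the visit differences; the group x visit term absorbs
        # group differences in change, so the residual variance is
        # group-centred with n - G degrees of freedom
        n, n_groups = len(diff), 2
        resid = diff - diff.groupby(groups).transform("mean")
        s2 = (resid ** 2).sum() / (n - n_groups)
        t = diff.mean() / np.sqrt(s2 / n)
        assert res.effect("visit")["F"] == pytest.approx(t ** 2, rel=1e-9)

    def test_incomplete_subjects_dropped_and_reported(self):
        values, groups = small_design(5, n_per_group=4, n_visits=3)
        values.iloc[0, 1] = np.nan
        res = dm.rm_anova(values, groups)
        assert res.dropped_subjects == ["s0"]
        assert res.n_subjects == 7

    def test_partial_eta2_definition(self):
        values, groups = small_design(6, shift=1.0)
        res = dm.rm_anova(values, groups)
        g = res.effect("group")
        subj = res.table.loc["subjects_within_group", "ss"]
        assert g["partial_eta2"] == pytest.approx(g["ss"] / (g["ss"] + subj))

    def test_too_few_groups_rejected(self):
        values = pd.DataFrame(np.ones((4, 3)))
        groups = pd.Series(["a"] * 4, index=values.index)
        with pytest.raises(dm.DataError):
            dm.rm_anova(values, groups)


class TestDeltaRegression:
    def test_perfect_fit_degenerates_to_point_interval(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = dm.delta_regression(x, 2 * x)
        assert res.b == pytest.approx(2.0)
        assert res.ci_low == res.ci_high == pytest.approx(2.0)
        assert res.p < 1e-100

    def test_three_point_closed_form(self):
        res = dm.delta_regression([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert res.b == pytest.approx(0.5)
        assert res.se == pytest.approx(0.866, abs=1e-3)
        assert res.p == pytest.approx(0.666, abs=1e-2)

    def test_agrees_with_statsmodels_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        res = dm.delta_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.b == pytest.approx(fit.params[1], abs=1e-10)
        lo, hi = fit.conf_int()[1]
        assert res.ci_low == pytest.approx(lo, abs=1e-10)
        assert res.ci_high == pytest.approx(hi, abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_ci_excludes_zero_iff_significant(self):
        rng = np.random.default_rng(1)
        for i in range(30):
            x = rng.normal(size=8)
            y = rng.normal(size=8) + (0.8 * x if i % 2 else 0)
            res = dm.delta_regression(x, y)
            excludes = res.ci_low > 0 or res.ci_high < 0
            assert excludes == (res.p < 0.05)

    def test_input_validation(self):
        with pytest.raises(dm.DataError, match=">= 3"):
            dm.delta_regression([1, 2], [1, 2])
        with pytest.raises(dm.DataError, match="variance"):
            dm.delta_regression([1, 1, 1], [1, 2, 3])


class TestClassification:
    def test_call_levels(self):
        assert call_level(0.01) == "significant"
        assert call_level(0.07) == "trend"
        assert call_level(0.5) == "ns"

    def test_trait_requires_clean_visit_effects(self):
        def fake(group_p, visit_p, inter_p):
            table = pd.DataFrame(
                {"p": [group_p, visit_p, inter_p]},
                index=["group", "visit", "group_x_visit"],
            )
            return dm.TraitResult(table=table, n_subjects=20, n_groups=2,
                                  n_visits=4, dropped_subjects=[])

        assert classify_trait(fake(0.01, 0.5, 0.5)) == "trait"
        assert classify_trait(fake(0.08, 0.5, 0.5)) == "trait_trend"
        assert classify_trait(fake(0.01, 0.01, 0.5)) == "ns"
        assert classify_trait(fake(0.01, 0.5, 0.03)) == "ns"

    def test_verdicts_recover_planted_labels(self):
        # single cohorts are noisy (10 patients); average a few replicates,
        # the full 20-cohort calibration lives in the acceptance suite
        sens = {"trait": [], "state": [], "prediction": []}
        for seed in (7, 8, 9, 10):
            ct, clinical, truth = dm.simulate_human_cohort(
                dm.HumanSimConfig(seed=seed))
            v = dm.human_validation(ct, clinical).verdicts
            sens["trait"].extend(
                v.loc[g, "trait_call"] == "trait"
                for g in truth.human_genes_of_class("trait"))
            sens["state"].extend(
                v.loc[g, "state_p"] < 0.05
                for g in truth.human_genes_of_class("state"))
            sens["prediction"].extend(
                v.loc[g, "pred_p"] < 0.05
                for g in truth.human_genes_of_class("prediction"))
        assert np.mean(sens["trait"]) >= 0.6
        assert np.mean(sens["state"]) >= 0.6
        assert np.mean(sens["prediction"]) >= 0.6
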