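"""Contrasts, SAM selection and the two candidate filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import depmark as dm
from depmark.datatypes import MIN_P
from tests.conftest import toy_matrix


def make_contrast(genes, p, sign, fc=None):
    p = np.asarray(p, dtype=float)
    sign = np.asarray(sign)
    if fc is None:
        fc = np.where(sign > 0, 2.0, 0.5)
    return pd.DataFrame(
        {"mean_a": 0.0, "mean_b": 0.0, "t": 0.0, "p": p, "fc": fc, "sign": sign},
        index=genes,
    )


class TestContrast:
    def test_identical_group_means_are_null(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = toy_matrix(values, ["A"] * 3 + ["B"] * 3)
        table = dm.contrast(m, "A", "B")
        assert table.iloc[0]["t"] == 0.0
        assert table.iloc[0]["p"] == 1.0
        assert table.iloc[0]["fc"] == 1.0

    def test_unit_log2_difference_doubles_fold_change(self):
        values = np.array([[2.0, 2.0, 1.0, 1.0]])
        m = toy_matrix(values, ["A", "A", "B", "B"])
        row = dm.contrast(m, "A", "B").iloc[0]
        assert row["fc"] == pytest.approx(2.0)
        assert row["sign"] == 1

    def test_closed_form_t_example(self):
        values = np.array([[8.0, 9.0, 10.0, 10.0, 11.0, 12.0]])
        m = toy_matrix(values, ["A"] * 3 + ["B"] * 3)
        row = dm.contrast(m, "A", "B").iloc[0]
        assert row["t"] == pytest.approx(-2.449, abs=1e-3)
        assert row["p"] == pytest.approx(0.0705, abs=1e-3)

    def test_agrees_with_scipy_pooled_t_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(40, 6))
        m = toy_matrix(values, ["A"] * 3 + ["B"] * 3)
        table = dm.contrast(m, "A", "B")
        t0, p0 = stats.ttest_ind(values[:, :3], values[:, 3:], axis=1,
                                 equal_var=True)
        np.testing.assert_allclose(table["t"], t0, atol=1e-10)
        np.testing.assert_allclose(table["p"], p0, atol=1e-10)

    def test_small_group_rejected(self):
        m = toy_matrix(np.zeros((2, 3)), ["A", "A", "B"])
        with pytest.raises(dm.DataError, match="'B'"):
            dm.contrast(m, "A", "B")

    def test_p_values_floored_not_zero(self):
        values = np.array([[0.0, 0.0, 5.0, 5.0]])
        m = toy_matrix(values, ["A", "A", "B", "B"])
        p = dm.contrast(m, "A", "B").iloc[0]["p"]
        assert 0 < p <= MIN_P * 10


class TestSam:
    def test_zero_s0_equal_sizes_reduces_to_t(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(100, 8)),
                              columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=values.columns)
        res = dm.sam_select(values, labels, s0=0.0, n_perm=50, seed=0)
        t0, _ = stats.ttest_ind(values.iloc[:, 4:], values.iloc[:, :4], axis=1,
                                equal_var=True)
        np.testing.assert_allclose(res.d.to_numpy(), t0, atol=1e-10)

    def test_null_data_selects_almost_nothing(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.normal(size=(400, 16)),
                                  columns=[f"s{i}" for i in range(16)])
            labels = pd.Series(["A"] * 8 + ["B"] * 8, index=values.columns)
            res = dm.sam_select(values, labels, target_fdr=0.01, n_perm=100,
                                seed=seed)
            sizes.append(len(res.selected))
        # null calibration: selections are rare and tiny (bounds from a
        # 50-replicate simulation of this SAM variant)
        assert np.mean(np.array(sizes) <= 2) >= 0.9
        assert np.mean(sizes) / 400 <= 0.01

    def test_planted_signal_fully_selected(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(1000, 16))
        values[:50, 8:] += 4.0  # 4 SD shift in 50 genes
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(1000)],
                             columns=[f"s{i}" for i in range(16)])
        labels = pd.Series(["A"] * 8 + ["B"] * 8, index=frame.columns)
        res = dm.sam_select(frame, labels, target_fdr=0.01, n_perm=100, seed=2)
        assert set(f"g{i}" for i in range(50)) <= set(res.selected)
        assert res.fdr <= 0.01

    def test_selected_set_shrinks_with_delta(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(300, 12))
        values[:20, 6:] += 2.0
        frame = pd.DataFrame(values, columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=frame.columns)
        res = dm.sam_select(frame, labels, n_perm=60, seed=3)
        assert (res.delta_table["n_called"].diff().dropna() <= 0).all()

    def test_exhaustive_permutations_for_tiny_designs(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(50, 6)),
                             columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=frame.columns)
        res = dm.sam_select(frame, labels, n_perm=200, seed=4)
        assert res.n_perm == 20  # C(6,3) distinct assignments

    def test_single_class_rejected(self):
        frame = pd.DataFrame(np.zeros((5, 4)), columns=list("abcd"))
        with pytest.raises(dm.DataError, match="two classes"):
            dm.sam_select(frame, pd.Series(["A"] * 4, index=frame.columns))


class TestReversalFilter:
    def test_truth_table(self):
        genes = ["kept_up", "flx_confound", "not_reversed", "stress_ns"]
        stress = make_contrast(genes, [0.01, 0.01, 0.01, 0.5], [1, 1, 1, 1])
        recovery = make_contrast(genes, [0.02, 0.02, 0.02, 0.02], [-1, -1, 1, -1])
        flx = make_contrast(genes, [0.8, 0.01, 0.8, 0.8], [1, 1, 1, 1])
        out = dm.reversal_filter(stress, recovery, flx)
        assert dm.kept_genes(out) == ["kept_up"]
        assert out.loc["kept_up", "stress_sign"] == 1
        assert out.loc["flx_confound", "reason"] == "flx_only_effect"
        assert out.loc["not_reversed", "reason"] == "not_reversed"
        assert out.loc["stress_ns", "reason"] == "stress_ns"

    def test_universe_mismatch_reports_difference(self):
        a = make_contrast(["g1", "g2"], [0.5, 0.5], [1, 1])
        b = make_contrast(["g1", "g3"], [0.5, 0.5], [1, 1])
        with pytest.raises(dm.DataError, match="g2"):
            dm.reversal_filter(a, b, a)

    def test_monotone_in_p_threshold(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(500)]
        tables = [
            make_contrast(genes, rng.uniform(size=500),
                          rng.choice([-1, 1], size=500))
            for _ in range(3)
        ]
        kept_tight = set(dm.kept_genes(dm.reversal_filter(*tables, p_thresh=0.05)))
        kept_loose = set(dm.kept_genes(dm.reversal_filter(*tables, p_thresh=0.2)))
        assert kept_tight <= kept_loose


class TestStressFilter:
    @pytest.mark.parametrize(
        "p,fc,kept",
        [
            (0.005, 1.3, True),
            (0.005, 1.0 / 1.3, True),   # symmetric on down-regulation
            (0.02, 2.0, False),
            (0.005, 1.1, False),
        ],
    )
    def test_threshold_rule(self, p, fc, kept):
        table = make_contrast(["g"], [p], [1 if fc >= 1 else -1], fc=[fc])
        assert (dm.kept_genes(dm.stress_filter(table)) == ["g"]) is kept

    def test_monotone_in_p_threshold(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(300)]
        fc = 2.0 ** rng.normal(0, 0.5, size=300)
        table = make_contrast(genes, rng.uniform(size=300),
                              np.where(fc >= 1, 1, -1), fc=fc)
        tight = set(dm.kept_genes(dm.stress_filter(table, p_thresh=0.01)))
        loose = set(dm.kept_genes(dm.stress_filter(table, p_thresh=0.05)))
        assert tight <= loose
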