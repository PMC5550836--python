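"""Signed ranking, hypergeometric tails, RRHO maps and overlap extraction."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import depmark as dm
from depmark.rrho import NEG_LOG10_CAP, RankedList


def ranked_from_scores(genes, scores):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    return RankedList(genes=np.asarray(genes, dtype=object)[order],
                      scores=np.asarray(scores, dtype=float)[order])


class TestSignedRank:
    def test_score_definition(self):
        table = pd.DataFrame(
            {"mean_a": 0, "mean_b": 0, "t": 0,
             "p": [0.01, 1.0, 0.001], "fc": [2.0, 1.0, 0.5],
             "sign": [1, 1, -1]},
            index=["up", "flat", "down"],
        )
        ranked = dm.signed_rank(table)
        scores = dict(zip(ranked.genes, ranked.scores))
        assert scores["up"] == pytest.approx(2.0)
        assert scores["flat"] == 0.0
        assert scores["down"] == pytest.approx(-3.0)
        assert list(ranked.genes) == ["up", "flat", "down"]  # down in the tail

    def test_zero_p_rejected(self):
        table = pd.DataFrame({"mean_a": 0, "mean_b": 0, "t": 0, "p": [0.0],
                              "fc": [2.0], "sign": [1]}, index=["g"])
        with pytest.raises(dm.DataError, match="floored"):
            dm.signed_rank(table)

    def test_ties_broken_by_gene_id(self):
        table = pd.DataFrame({"mean_a": 0, "mean_b": 0, "t": 0,
                              "p": [0.5, 0.5], "fc": [2.0, 2.0],
                              "sign": [1, 1]}, index=["b", "a"])
        assert list(dm.signed_rank(table).genes) == ["a", "b"]


def enumeration_tail(N, K, n, k, lower=False):
    """Oracle: count draws of size n with overlap >= k (or <= k) among all
    C(N, n) subsets."""
    successes = set(range(K))
    good = 0
    for draw in itertools.combinations(range(N), n):
        o = len(successes & set(draw))
        good += (o <= k) if lower else (o >= k)
    return good / comb(N, n)


class TestHypergeomTail:
    def test_exact_small_cases(self):
        assert dm.hypergeom_tail(10, 5, 5, 5) == pytest.approx(1 / 252)
        assert dm.hypergeom_tail(4, 2, 2, 2) == pytest.approx(1 / 6)
        assert dm.hypergeom_tail(7, 3, 4, 0) == 1.0  # k = 0: certain event

    def test_matches_enumeration_oracle(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert dm.hypergeom_tail(N, K, n, k) == pytest.approx(
                            enumeration_tail(N, K, n, k), abs=1e-12), (N, K, n, k)

    def test_matches_scipy_cross_check(self):
        for N, K, n, k in [(1000, 40, 60, 10), (100000, 500, 700, 30)]:
            expected = stats.hypergeom.sf(k - 1, N, K, n)
            assert dm.hypergeom_tail(N, K, n, k) == pytest.approx(expected,
                                                                  rel=1e-9)

    def test_log_tail_stable_at_extreme_overlap(self):
        # overlap far beyond expectation: p underflows linear doubles
        log_p = dm.log_hypergeom_tail(100000, 1000, 1000, 1000)
        assert np.isfinite(log_p)
        assert -log_p / np.log(10) > 320

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(dm.DataError):
            dm.hypergeom_tail(10, 12, 5, 2)
        with pytest.raises(dm.DataError):
            dm.hypergeom_tail(10, 5, 5, 6)


class TestRRHOMap:
    def test_identical_lists_peak_on_diagonal(self):
        genes = [f"g{i}" for i in range(200)]
        scores = np.linspace(3, -3, 200)
        la = ranked_from_scores(genes, scores)
        m = dm.rrho_map(la, la, step=1)
        # perfect concordance: k(i, i) = i along the diagonal
        np.testing.assert_array_equal(np.diag(m.counts), np.arange(1, 201))
        s = dm.rrho_summary(m)
        assert s.argmax[0] == s.argmax[1]
        assert s.quadrant == "up-up"

    def test_reversed_lists_are_head_tail_enriched(self):
        genes = [f"g{i}" for i in range(200)]
        scores = np.linspace(3, -3, 200)
        la = ranked_from_scores(genes, scores)
        lb = RankedList(genes=la.genes[::-1].copy(), scores=la.scores.copy())
        m = dm.rrho_map(la, lb, step=1)
        # diagonal cells (i + i <= N) have zero overlap -> under-enriched
        n_half = 100
        assert (np.diag(m.sign)[: n_half - 1] == -1).all()
        assert np.diag(m.neg_log_p)[n_half // 2] > 3  # strongly depleted
        # head-vs-tail over-enrichment surfaces through the discordant
        # extraction (A's head against B read from its tail)
        genes = dm.overlap_genes(m, la, lb, "discordant")
        head = set(la.genes[:la.n_positive])
        assert head <= set(genes)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        genes = np.array([f"g{i}" for i in range(120)], dtype=object)
        scores = np.linspace(2, -2, 120)
        la = RankedList(genes=genes[rng.permutation(120)], scores=scores)
        lb = RankedList(genes=genes[rng.permutation(120)], scores=scores)
        mab = dm.rrho_map(la, lb, step=5)
        mba = dm.rrho_map(lb, la, step=5)
        np.testing.assert_allclose(mab.neg_log_p, mba.neg_log_p.T, atol=1e-10)
        np.testing.assert_array_equal(mab.sign, mba.sign.T)

    def test_overlap_counts_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        genes = np.array([f"g{i}" for i in range(150)], dtype=object)
        scores = np.linspace(2, -2, 150)
        la = RankedList(genes=genes[rng.permutation(150)], scores=scores)
        lb = RankedList(genes=genes[rng.permutation(150)], scores=scores)
        m = dm.rrho_map(la, lb, step=3)
        assert (np.diff(m.counts, axis=0) >= 0).all()
        assert (np.diff(m.counts, axis=1) >= 0).all()
        assert (m.counts <= np.minimum(m.thresholds_a[:, None],
                                       m.thresholds_b[None, :])).all()

    def test_values_capped(self):
        genes = [f"g{i}" for i in range(3000)]
        scores = np.linspace(3, -3, 3000)
        la = ranked_from_scores(genes, scores)
        m = dm.rrho_map(la, la, step=30)
        assert m.neg_log_p.max() <= NEG_LOG10_CAP

    def test_universe_mismatch_rejected(self):
        la = ranked_from_scores(["a", "b"], [1.0, -1.0])
        lb = ranked_from_scores(["a", "c"], [1.0, -1.0])
        with pytest.raises(dm.DataError, match="universe"):
            dm.rrho_map(la, lb)

    def test_over_only_mode_scores_upper_tail_everywhere(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.linspace(1, -1, 100)
        la = ranked_from_scores(genes, scores)
        lb = RankedList(genes=la.genes[::-1].copy(), scores=la.scores.copy())
        m = dm.rrho_map(la, lb, step=10, mode="over_only")
        under = m.counts < (m.thresholds_a[:, None] * m.thresholds_b[None, :]
                            / m.n_genes)
        # under-enriched cells get ~0 in over-only mode (upper tail ~ 1)
        assert m.neg_log_p[under].max() < 0.5


class TestSummaryAndOverlap:
    def test_single_cell_map(self):
        la = ranked_from_scores(["a", "b"], [1.0, -1.0])
        m = dm.rrho_map(la, la, step=2)
        s = dm.rrho_summary(m)
        assert s.argmax == (2, 2)

    def test_null_percentile_reported(self):
        genes = [f"g{i}" for i in range(100)]
        la = ranked_from_scores(genes, np.linspace(1, -1, 100))
        m = dm.rrho_map(la, la, step=5)
        s = dm.rrho_summary(m, null_maxima=np.array([1.0, 2.0, 3.0]))
        assert s.null_percentile == 100.0

    def test_identical_lists_return_top_segment(self):
        genes = [f"g{i}" for i in range(100)]
        scores = np.linspace(3, -3, 100)  # half positive, half negative
        la = ranked_from_scores(genes, scores)
        m = dm.rrho_map(la, la, step=1)
        got = dm.overlap_genes(m, la, la, "concordant_up")
        i = len(got)
        assert set(got) == set(la.genes[:i])
        assert 0 < i <= la.n_positive

    def test_disjoint_top_segments_give_empty_list(self):
        # A's head is B's tail and vice versa -> no concordant overlap signal
        genes = np.array([f"g{i}" for i in range(40)], dtype=object)
        scores = np.linspace(2, -2, 40)
        la = RankedList(genes=genes, scores=scores)
        lb = RankedList(genes=genes[::-1].copy(), scores=scores)
        m = dm.rrho_map(la, lb, step=1)
        with pytest.warns(UserWarning, match="empty overlap"):
            got = dm.overlap_genes(m, la, lb, "concordant_up")
        assert got == []

    def test_planted_concordant_recovery(self, mouse_data, mouse_result):
        _, _, truth = mouse_data
        planted = set(truth.genes_of_class("concordant_up")) | set(
            truth.genes_of_class("concordant_down"))
        lists = mouse_result.rrho_genes[("blood", "DG")]
        got = set(lists["concordant_up"]) | set(lists["concordant_down"])
        assert len(planted & got) / len(planted) >= 0.8

    def test_discordant_mode_finds_antiphase_genes(self, mouse_data, mouse_result):
        _, _, truth = mouse_data
        planted = set(truth.genes_of_class("discordant_blood_brain"))
        got = set(mouse_result.rrho_genes[("blood", "DG")]["discordant"])
        assert len(planted & got) / len(planted) >= 0.8
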