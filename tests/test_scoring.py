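"""Core scoring: rank profiles and directed/bidirectional/undirected scores.

Derived expectations were computed with the brute-force oracle below (a
straight transcription of the mean-rank formulas, independent of the package
code paths) before being frozen here.
"""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rankscore import (
    DegenerateBoundsError,
    ExpressionMatrix,
    GeneSignature,
    ScoringError,
    rank_genes,
    rank_matrix,
    score_bidirectional,
    score_directed,
    score_matrix,
    score_signature,
    score_undirected,
)

# ---------------------------------------------------------------- oracles


def oracle_directed(set_ranks, n_total, direction="up"):
    """Independent evaluation of the directed normalised mean-rank score."""
    r = [n_total + 1 - x for x in set_ranks] if direction == "down" else list(set_ranks)
    n = len(r)
    raw = sum(r) / n
    s_min = (n + 1) / 2
    s_max = (2 * n_total - n + 1) / 2
    return (raw - s_min) / (s_max - s_min)


def oracle_undirected(set_ranks, n_total):
    """Independent evaluation of the undirected (median-centred) score.

    Returns None where the verbatim bounds collapse (S_max == S_min), which
    happens not only for the whole universe but also e.g. at N=4, n=3.
    """
    c = math.ceil(n_total / 2)
    rhat = [abs(x - c) for x in set_ranks]
    n = len(rhat)
    raw = sum(rhat) / n
    s_min = (math.ceil(n / 2) + 1) / 2
    s_max = (n_total - math.ceil(n / 2) + 1) / 2
    if s_max == s_min:
        return None
    return (raw - s_min) / (s_max - s_min)


def em_with_ranks(n_total):
    """Expression ladder where gene gK holds rank K."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": np.arange(1.0, n_total + 1)},
                     index=[f"g{i}" for i in range(1, n_total + 1)])
    )


# ------------------------------------------------------------- rank_genes


class TestRankGenes:
    def test_simple_ordering(self):
        em = ExpressionMatrix(pd.DataFrame({"s": [5.0, 1.0, 3.0]},
                                           index=["A", "B", "C"]))
        rp = rank_genes(em, "s")
        assert rp.ranks.to_dict() == {"A": 3.0, "B": 1.0, "C": 2.0}
        assert rp.n_total == 3

    def test_ties_get_average_rank(self):
        em = ExpressionMatrix(pd.DataFrame({"s": [2.0, 2.0, 1.0]},
                                           index=["A", "B", "C"]))
        rp = rank_genes(em, "s")
        assert rp.ranks.to_dict() == {"A": 2.5, "B": 2.5, "C": 1.0}

    def test_rank_sum_invariant_with_ties(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 5, size=30).astype(float)  # many ties
        em = ExpressionMatrix(pd.DataFrame({"s": vals},
                                           index=[f"g{i}" for i in range(30)]))
        rp = rank_genes(em, "s")
        assert rp.ranks.sum() == 30 * 31 / 2

    def test_log_transform_gives_identical_profile(self, random_em):
        logged = ExpressionMatrix(np.log2(random_em.data + 1),
                                  log_transformed=True)
        for s in random_em.sample_ids:
            pd.testing.assert_series_equal(
                rank_genes(random_em, s).ranks, rank_genes(logged, s).ranks
            )

    def test_unknown_sample(self, random_em):
        with pytest.raises(KeyError):
            rank_genes(random_em, "ghost")

    def test_single_gene_rejected(self):
        em = ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["g"]))
        with pytest.raises(ScoringError):
            rank_genes(em, "s")

    def test_rank_matrix_matches_per_sample(self, random_em):
        rm = rank_matrix(random_em)
        for s in random_em.sample_ids:
            assert (rm[s] == rank_genes(random_em, s).ranks).all()


# --------------------------------------------------------- score_directed


class TestScoreDirected:
    def test_maximal_configuration(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_directed(rp, ["g9", "g10"], "up")
        assert res.raw_up == 9.5
        assert res.bounds["up"] == (1.5, 9.5)
        assert res.norm_up == 1.0

    def test_minimal_configuration(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        assert score_directed(rp, ["g1", "g2"], "up").norm_up == 0.0

    def test_mid_configuration_frozen_oracle_value(self):
        # [DERIVED] oracle_directed({3,7}, 10) == 0.4375
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_directed(rp, ["g3", "g7"], "up")
        assert res.raw_up == 5.0
        assert res.norm_up == 0.4375
        assert res.norm_up == oracle_directed({3, 7}, 10)

    def test_down_direction_reverses_ranks(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_directed(rp, ["g1", "g2"], "down")
        # lowest-abundance genes are maximal for a down-set
        assert res.norm_down == 1.0
        assert res.raw_down == 9.5

    def test_exhaustive_oracle_equivalence_small_universes(self):
        for n_total in range(2, 9):
            rp = rank_genes(em_with_ranks(n_total), "s1")
            genes = [f"g{i}" for i in range(1, n_total + 1)]
            for size in range(1, n_total):
                for combo in itertools.combinations(range(1, n_total + 1), size):
                    gset = [f"g{i}" for i in combo]
                    for direction in ("up", "down"):
                        got = score_directed(rp, gset, direction)
                        want = oracle_directed(set(combo), n_total, direction)
                        assert got.total == pytest.approx(want, abs=1e-12)
                        assert 0.0 <= got.total <= 1.0

    def test_missing_genes_are_dropped(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_directed(rp, ["g9", "g10", "NOT_THERE"], "up")
        assert res.n_used["up"] == 2
        assert res.norm_up == 1.0

    def test_no_genes_present_raises_named_error(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        with pytest.raises(ScoringError, match="mysig"):
            score_directed(rp, ["x", "y"], "up", signature_name="mysig")

    def test_whole_universe_degenerate(self):
        rp = rank_genes(em_with_ranks(5), "s1")
        with pytest.raises(DegenerateBoundsError):
            score_directed(rp, [f"g{i}" for i in range(1, 6)], "up")

    def test_center_flag_shifts_by_half(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        plain = score_directed(rp, ["g3", "g7"], "up")
        centred = score_directed(rp, ["g3", "g7"], "up", center=True)
        assert centred.total == plain.total - 0.5


# ---------------------------------------------------- score_bidirectional


class TestScoreBidirectional:
    def test_concordant_extreme_scores_one(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        sig = GeneSignature("sig", "bidirectional",
                            frozenset({"g9", "g10"}), frozenset({"g1", "g2"}))
        assert score_bidirectional(rp, sig).total == 1.0

    def test_anticoncordant_extreme_scores_minus_one(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        sig = GeneSignature("sig", "bidirectional",
                            frozenset({"g1", "g2"}), frozenset({"g9", "g10"}))
        assert score_bidirectional(rp, sig).total == -1.0

    def test_mixed_case_frozen_oracle_value(self):
        # [DERIVED] up at abundance ranks {3,7}: norm 0.4375; down at {4,8}:
        # reversed ranks {7,3}, norm 0.4375 -> total (0.4375-0.5)*2 = -0.125.
        rp = rank_genes(em_with_ranks(10), "s1")
        sig = GeneSignature("sig", "bidirectional",
                            frozenset({"g3", "g7"}), frozenset({"g4", "g8"}))
        res = score_bidirectional(rp, sig)
        want = (oracle_directed({3, 7}, 10) - 0.5) + (
            oracle_directed({4, 8}, 10, "down") - 0.5)
        assert res.total == pytest.approx(want)
        assert res.total == pytest.approx(-0.125)
        # and a down-set at {6,8} gives the steeper -0.25
        sig2 = GeneSignature("sig2", "bidirectional",
                             frozenset({"g3", "g7"}), frozenset({"g6", "g8"}))
        assert score_bidirectional(rp, sig2).total == pytest.approx(-0.25)

    def test_uncentered_total_is_plain_sum(self):
        rp = rank_genes(em_with_ranks(10), "s1")
        sig = GeneSignature("sig", "bidirectional",
                            frozenset({"g3", "g7"}), frozenset({"g4", "g8"}))
        res = score_bidirectional(rp, sig, center=False)
        assert res.total == pytest.approx(res.norm_up + res.norm_down)

    def test_total_within_unit_interval_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            perm = rng.permutation(20) + 1.0
            em = ExpressionMatrix(pd.DataFrame(
                {"s1": perm}, index=[f"g{i}" for i in range(1, 21)]))
            rp = rank_genes(em, "s1")
            genes = rng.choice(em.gene_ids, size=8, replace=False)
            sig = GeneSignature("r", "bidirectional",
                                frozenset(genes[:4]), frozenset(genes[4:]))
            assert -1.0 <= score_bidirectional(rp, sig).total <= 1.0

    def test_wrong_mode_rejected(self, ladder_em):
        rp = rank_genes(ladder_em, "s1")
        sig = GeneSignature("u", "up", frozenset({"g1"}))
        with pytest.raises(ScoringError):
            score_bidirectional(rp, sig)


# ------------------------------------------------------- score_undirected


class TestScoreUndirected:
    def test_extreme_set_frozen_oracle_value(self):
        # [DERIVED] ranks {1,10}, N=10: R^ = {4,5}, raw 4.5, bounds (1,5)
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_undirected(rp, ["g1", "g10"])
        assert res.raw_undirected == 4.5
        assert res.bounds["undirected"] == (1.0, 5.0)
        assert res.norm_undirected == 0.875
        assert res.norm_undirected == oracle_undirected({1, 10}, 10)

    def test_central_set_goes_below_zero_unclamped(self):
        # [DERIVED] ranks {5,6}: raw 0.5 -> norm -0.125 (verbatim bounds,
        # deliberately not clamped)
        rp = rank_genes(em_with_ranks(10), "s1")
        res = score_undirected(rp, ["g5", "g6"])
        assert res.norm_undirected == -0.125

    def test_theoretical_max_not_attainable_at_n2(self):
        # [DERIVED] brute force over all 2-subsets of 1..10: max mean 4.5 < S_max 5
        best = max(
            (abs(a - 5) + abs(b - 5)) / 2
            for a, b in itertools.combinations(range(1, 11), 2)
        )
        assert best == 4.5
        rp = rank_genes(em_with_ranks(10), "s1")
        assert score_undirected(rp, ["g1", "g10"]).norm_undirected < 1.0

    def test_whole_universe_degenerate(self):
        # [DERIVED] N=10, n=10: S_min = S_max = 3
        rp = rank_genes(em_with_ranks(10), "s1")
        with pytest.raises(DegenerateBoundsError):
            score_undirected(rp, [f"g{i}" for i in range(1, 11)])

    def test_exhaustive_oracle_equivalence_small_universes(self):
        for n_total in range(4, 9):
            rp = rank_genes(em_with_ranks(n_total), "s1")
            for size in range(1, n_total):
                for combo in itertools.combinations(range(1, n_total + 1), size):
                    want = oracle_undirected(set(combo), n_total)
                    gset = [f"g{i}" for i in combo]
                    if want is None:
                        with pytest.raises(DegenerateBoundsError):
                            score_undirected(rp, gset)
                        continue
                    got = score_undirected(rp, gset)
                    assert got.total == pytest.approx(want, abs=1e-12)


# ----------------------------------------------------------- score_matrix


class TestScoreMatrix:
    def test_one_row_per_pair(self, random_em, bidir_sig):
        table = score_matrix(random_em, [bidir_sig])
        assert len(table) == random_em.n_samples
        assert set(table["signature"]) == {"emt"}

    def test_empty_signature_list(self, random_em):
        assert score_matrix(random_em, []).empty

    def test_sample_independence_exact(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            rng.lognormal(1.0, 1.2, size=(80, 40)),
            index=[f"g{i:03d}" for i in range(80)],
            columns=[f"s{j:02d}" for j in range(40)],
        )
        em = ExpressionMatrix(data)
        sig = GeneSignature("x", "bidirectional",
                            frozenset([f"g{i:03d}" for i in range(0, 10)]),
                            frozenset([f"g{i:03d}" for i in range(10, 20)]))
        full = score_matrix(em, [sig]).set_index("sample_id")["total_score"]
        solo = score_matrix(em.subset(samples=["s05"]), [sig])
        assert solo["total_score"].iloc[0] == full["s05"]  # bit-for-bit

    def test_failed_pair_skipped_not_fatal(self, random_em, caplog):
        good = GeneSignature("ok", "up", frozenset({"g001", "g002"}))
        bad = GeneSignature("ghost", "up", frozenset({"absent"}))
        table = score_matrix(random_em, [good, bad])
        assert set(table["signature"]) == {"ok"}

    def test_dispersion_columns_present(self, random_em, bidir_sig):
        table = score_matrix(random_em, [bidir_sig], dispersion=True)
        assert {"mad_up", "mad_down", "mad_total"} <= set(table.columns)
        assert (table["mad_total"] >= 0).all()

    def test_mixed_modes(self, random_em, bidir_sig):
        solo = GeneSignature("solo", "up", frozenset({"g003", "g004"}))
        undir = GeneSignature("und", "undirected", frozenset({"g005", "g006"}))
        table = score_matrix(random_em, [bidir_sig, solo, undir])
        assert len(table) == 3 * random_em.n_samples
        assert set(table["mode"]) == {"bidirectional", "up", "undirected"}
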