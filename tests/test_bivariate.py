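import numpy as np
import pytest

from bivarscan import (
    aggregate_gene_scores,
    enumerate_pairs,
    pair_cv_score,
    pair_statistics,
    score_all_pairs,
    transfer_summary,
)
from bivarscan.bivariate import PairScoreTensor, stratified_splits
from bivarscan.data_io import StudyCollection

from conftest import make_dataset, random_tensor
from oracles import cv_sum_oracle, svm_cv_oracle, welch_oracle


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,count", [(2, 1), (10, 45), (30, 435)])
    def test_pair_count_is_n_choose_2(self, n, count):
        genes = [f"G{i:03d}" for i in range(n)]
        pairs = enumerate_pairs(genes)
        assert len(pairs) == count

    def test_canonical_lexicographic_order(self):
        pairs = enumerate_pairs(["C", "A", "B"])
        assert pairs == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["A"])


class TestPairCVScore:
    def test_wide_margin_pair_scores_one(self):
        rng = np.random.default_rng(0)
        sep = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])
        noise = rng.normal(size=20)
        ds = make_dataset(np.vstack([sep, noise]), [0] * 10 + [1] * 10)
        assert pair_cv_score(ds, ("G1", "G2"), seed=0) == 1.0

    def test_constant_pair_matches_majority_prediction_oracle(self):
        # both genes constant: every training fold's SVM sees identical
        # points and can only predict the training majority class, so each
        # fold's accuracy is the majority class's share of the test fold
        ds = make_dataset(np.full((2, 14), 3.0), [0] * 6 + [1] * 8)
        got = pair_cv_score(ds, ("G1", "G2"), seed=0)
        y = ds.labels.to_numpy()
        accs = []
        for train, test in stratified_splits(y, 5, 0):
            majority = int(np.bincount(y[train]).argmax())
            accs.append(float(np.mean(y[test] == majority)))
        assert got == pytest.approx(np.mean(accs))
        assert abs(got - 8 / 14) < 0.15  # near the label-balance chance level

    def test_matches_convex_solver_oracle_on_printed_fixture(self):
        # 10 samples, 2 genes, values fixed here; the oracle refits the
        # same soft-margin classifier per fold with SLSQP
        values = np.array(
            [
                [2.1, 1.8, 2.5, 3.0, 1.2, 4.8, 5.1, 4.2, 3.9, 5.5],
                [0.5, 1.1, 0.8, 1.9, 0.2, 1.0, 0.7, 1.5, 0.3, 1.8],
            ]
        )
        labels = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        ds = make_dataset(values, labels)
        got = pair_cv_score(ds, ("G1", "G2"), seed=3)
        y = np.array(labels)
        splits = stratified_splits(y, 5, 3)
        oracle = svm_cv_oracle(values.T, y, splits, 100.0)
        assert got == pytest.approx(oracle)

    def test_class_smaller_than_fold_count_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(2, 7)),
                          [0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="folds"):
            pair_cv_score(ds, ("G1", "G2"), folds=5, seed=0)

    def test_unknown_gene_rejected(self):
        ds = make_dataset(np.ones((2, 10)) + np.random.default_rng(0).normal(size=(2, 10)),
                          [0] * 5 + [1] * 5)
        with pytest.raises(KeyError, match="NOPE"):
            pair_cv_score(ds, ("G1", "NOPE"), seed=0)


def _two_cohorts(seed=0, n_genes=5, n=16):
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    sets = []
    for name in ("c1", "c2"):
        sets.append(
            make_dataset(rng.normal(size=(n_genes, n)), [0] * (n // 2) + [1] * (n // 2),
                         genes=genes, name=name)
        )
    return StudyCollection(datasets=sets, gene_universe=genes)


class TestScoreAllPairs:
    def test_tensor_shape_contract(self):
        coll = _two_cohorts()
        tensor = score_all_pairs(coll, coll.gene_universe, seed=0)
        assert len(tensor.pairs) == 10
        assert tensor.scores.shape == (10, 2)
        assert ((tensor.scores >= 0) & (tensor.scores <= 1)).all()

    def test_identical_seed_gives_identical_tensor(self):
        coll = _two_cohorts()
        a = score_all_pairs(coll, coll.gene_universe, seed=5)
        b = score_all_pairs(coll, coll.gene_universe, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_cell_equals_standalone_pair_score(self):
        coll = _two_cohorts()
        tensor = score_all_pairs(coll, coll.gene_universe, seed=2)
        pair = ("G2", "G4")
        expected = [pair_cv_score(ds, pair, seed=2) for ds in coll]
        np.testing.assert_allclose(tensor.score_of(pair), expected)

    def test_all_null_data_scores_near_chance(self):
        # balanced labels, pure noise: mean tensor score should sit within
        # Monte-Carlo spread of 0.5
        means = []
        for seed in range(3):
            coll = _two_cohorts(seed=seed, n_genes=6, n=20)
            tensor = score_all_pairs(coll, coll.gene_universe, seed=seed)
            means.append(tensor.scores.mean())
        assert abs(np.mean(means) - 0.5) < 0.06


class TestAggregateGeneScores:
    def test_all_cells_below_threshold_score_zero(self, toy_tensor):
        ranking = aggregate_gene_scores(toy_tensor, threshold=0.99)
        assert (ranking.scores == 0).all()

    def test_single_passing_cell_credits_both_genes(self):
        genes = ["A", "B"]
        tensor = PairScoreTensor(
            genes=genes, pairs=[("A", "B")], dataset_names=["d1"],
            scores=np.array([[0.9]]), cv_folds=5, svm_c=100.0, seed=0,
        )
        ranking = aggregate_gene_scores(tensor, threshold=0.7)
        assert ranking.scores["A"] == pytest.approx(0.9)
        assert ranking.scores["B"] == pytest.approx(0.9)

    def test_matches_double_loop_oracle(self, toy_tensor):
        ranking = aggregate_gene_scores(toy_tensor, threshold=0.7)
        oracle = cv_sum_oracle(
            toy_tensor.pairs, toy_tensor.scores, toy_tensor.genes, 0.7
        )
        for g in toy_tensor.genes:
            assert ranking.scores[g] == pytest.approx(oracle[g])

    def test_strict_inequality_at_boundary(self):
        tensor = PairScoreTensor(
            genes=["A", "B"], pairs=[("A", "B")], dataset_names=["d1"],
            scores=np.array([[0.70]]), cv_folds=5, svm_c=100.0, seed=0,
        )
        assert (aggregate_gene_scores(tensor, threshold=0.70).scores == 0).all()

    def test_threshold_monotonicity_per_gene(self):
        for seed in range(5):
            tensor = random_tensor(seed)
            lo = aggregate_gene_scores(tensor, threshold=0.4).scores
            hi = aggregate_gene_scores(tensor, threshold=0.8).scores
            assert (lo >= hi - 1e-12).all()

    def test_sum_conservation(self):
        for seed in range(5):
            tensor = random_tensor(seed)
            ranking = aggregate_gene_scores(tensor, threshold=0.6)
            passing = tensor.scores[tensor.scores > 0.6].sum()
            assert ranking.scores.sum() == pytest.approx(2 * passing)

    def test_pair_sum_mode_uses_cross_cohort_mean(self, toy_tensor):
        # B sits in (A,B) (mean 0.75, passes) and (B,C) (mean 0.725,
        # passes); in pair_sum mode both pairs credit ALL their cells,
        # including the 0.60 and 0.50 cells that fail per-cell thresholding
        ranking = aggregate_gene_scores(toy_tensor, threshold=0.7, mode="pair_sum")
        assert ranking.scores["B"] == pytest.approx((0.90 + 0.60) + (0.50 + 0.95))

    def test_rank_table_orders_descending_with_lexicographic_ties(self, toy_tensor):
        table = aggregate_gene_scores(toy_tensor, threshold=0.7).table()
        assert list(table["cv_sum"]) == sorted(table["cv_sum"], reverse=True)
        assert set(table.columns) == {"gene", "cv_sum", "rank"}


class TestPairStatistics:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.5), 1.0),
            ((0.9, 0.8, 0.6), 0.81 - 0.36),
        ],
    )
    def test_selectivity_from_squared_scores(self, scores, expected):
        tensor = PairScoreTensor(
            genes=["A", "B"], pairs=[("A", "B")],
            dataset_names=["d1", "d2", "d3"],
            scores=np.array([scores]), cv_folds=5, svm_c=100.0, seed=0,
        )
        stats = pair_statistics(tensor)
        assert stats.loc[0, "selectivity"] == pytest.approx(expected)
        assert stats.loc[0, "aggregate"] == pytest.approx(sum(scores))

    def test_selectivity_bounds_and_zero_condition(self):
        for seed in range(5):
            tensor = random_tensor(seed)
            stats = pair_statistics(tensor)
            assert ((stats["selectivity"] >= 0) & (stats["selectivity"] <= 1)).all()
            sq = tensor.scores**2
            equal = np.isclose(sq.max(axis=1), sq.min(axis=1))
            np.testing.assert_array_equal(
                np.isclose(stats["selectivity"].to_numpy(), 0.0), equal
            )


class TestTransferSummary:
    def _tensor(self, col_a, col_b):
        n = len(col_a)
        genes = [f"G{i + 1}" for i in range(n + 1)]
        pairs = enumerate_pairs(genes)[:n]
        # only the first n pairs carry our fixture scores; rest unused
        genes_used = sorted({g for p in pairs for g in p})
        all_pairs = enumerate_pairs(genes)
        scores = np.zeros((len(all_pairs), 2))
        for i, p in enumerate(pairs):
            scores[all_pairs.index(p)] = [col_a[i], col_b[i]]
        return PairScoreTensor(
            genes=genes, pairs=all_pairs, dataset_names=["src", "dst"],
            scores=scores, cv_folds=5, svm_c=100.0, seed=0,
        )

    def test_identical_score_vectors_give_p_one(self):
        col = [0.9, 0.8, 0.85, 0.75, 0.95]
        tensor = self._tensor(col, col)
        out = transfer_summary(tensor, "src", threshold=0.7)
        assert out.loc["dst", "mean_score"] == pytest.approx(np.mean(col))
        assert out.loc["dst", "welch_p"] == pytest.approx(1.0)

    def test_welch_t_and_p_match_closed_form_oracle(self):
        a = [0.92, 0.88, 0.95, 0.81, 0.90]
        b = [0.61, 0.72, 0.55, 0.68, 0.64]
        tensor = self._tensor(a, b)
        out = transfer_summary(tensor, "src", threshold=0.7)
        t_exp, p_exp = welch_oracle(np.array(a), np.array(b))
        assert out.loc["dst", "welch_t"] == pytest.approx(t_exp)
        assert out.loc["dst", "welch_p"] == pytest.approx(p_exp)
        assert out.loc["src", "mean_score"] == pytest.approx(np.mean(a))

    def test_empty_passing_set_rejected(self):
        tensor = self._tensor([0.1, 0.2, 0.1, 0.15, 0.12], [0.5] * 5)
        with pytest.raises(ValueError, match="no pairs pass"):
            transfer_summary(tensor, "src", threshold=0.7)
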