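import numpy as np
import pytest
from scipy.stats import special_ortho_group

from drivergraph import (
    CountMatrix,
    classification_metrics,
    dge_baseline_ranking,
    lisi,
    prediction_score,
    rank_metrics,
    transition_score,
)
from drivergraph.data_core import ValidationError
from drivergraph.evaluation import dge_candidate_ranks, ranks_of_labels


class TestClassificationMetrics:
    def test_perfect_predictor(self):
        labels = np.arange(6)
        probs = np.full((6, 6), 0.01)
        probs[np.arange(6), labels] = 0.95
        rep = classification_metrics(probs, labels)
        assert rep.top_1 == rep.top_5 == rep.macro_f1 == rep.auroc == 1.0
        assert rep.mean_rank == 1.0

    def test_top5_nests_top1(self, rng):
        probs = rng.dirichlet(np.ones(12), size=300)
        labels = rng.integers(0, 12, size=300)
        rep = classification_metrics(probs, labels)
        assert rep.top_5 >= rep.top_1
        assert 1 <= rep.mean_rank <= 12

    def test_absent_class_skipped_with_warning(self, caplog):
        probs = np.array([[0.6, 0.2, 0.2], [0.1, 0.8, 0.1]])
        labels = np.array([0, 1])  # class 2 never appears
        with caplog.at_level("WARNING"):
            rep = classification_metrics(probs, labels)
        assert "skipped" in caplog.text
        assert np.isfinite(rep.auroc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(np.empty((0, 3)), np.empty(0, dtype=int))


class TestRankMetrics:
    def test_rank_of_true_label_tie_break(self):
        probs = np.array([[0.5, 0.3, 0.2]])
        assert ranks_of_labels(probs, np.array([1]))[0] == 2
        # exact ties resolve by candidate index
        probs = np.full((1, 4), 0.25)
        assert ranks_of_labels(probs, np.array([2]))[0] == 3

    def test_dual_driver_order_invariance(self):
        probs = np.zeros((1, 12))
        probs[0, 3] = 0.5  # rank 1
        probs[0, 7] = 0.3  # rank 2
        a = rank_metrics(probs, [3], second_labels=[7])
        b = rank_metrics(probs, [7], second_labels=[3])
        assert a["perturbation1_ranks"][0] == b["perturbation1_ranks"][0] == 1
        assert a["perturbation2_ranks"][0] == b["perturbation2_ranks"][0] == 2

    def test_random_predictor_mean_rank(self, rng):
        K, n = 20, 10000
        probs = rng.dirichlet(np.ones(K), size=n)
        labels = rng.integers(0, K, size=n)
        r = rank_metrics(probs, labels)
        se = np.sqrt((K**2 - 1) / 12 / n)
        assert abs(r["mean_rank"] - (K + 1) / 2) < 3 * se


class TestLisi:
    def test_single_label_scores_zero(self, rng, caplog):
        emb = rng.standard_normal((100, 3))
        with caplog.at_level("WARNING"):
            scores = lisi(emb, np.zeros(100, dtype=int))
        assert np.all(scores == 0)

    def test_perfect_interleaving_scores_one(self):
        x = np.arange(200, dtype=float)[:, None]
        labels = np.tile([0, 1], 100)
        scores = lisi(x, labels, perplexity=30)
        assert scores.mean() > 0.95

    def test_separated_clusters_score_near_zero(self, rng):
        a = rng.standard_normal((60, 2))
        b = rng.standard_normal((60, 2)) + 100
        scores = lisi(np.vstack([a, b]), np.repeat([0, 1], 60), perplexity=15)
        assert scores.mean() < 0.05

    def test_bounds_and_rotation_invariance(self, rng):
        emb = rng.standard_normal((150, 5))
        labels = rng.integers(0, 3, size=150)
        s1 = lisi(emb, labels)
        assert np.all((s1 >= 0) & (s1 <= 1))
        R = special_ortho_group.rvs(5, random_state=1)
        s2 = lisi(emb @ R, labels)
        np.testing.assert_allclose(s1, s2, atol=1e-8)


class TestTransitionScore:
    def test_zero_for_identical_profiles(self, rng):
        vals = rng.random((4, 6))
        genes = [f"g{i}" for i in range(6)]
        out = transition_score(vals, vals, {"setA": genes[:3]}, gene_ids=genes)
        np.testing.assert_allclose(out["setA"], 0.0)

    def test_mean_difference_formula(self):
        genes = ["m1", "m2", "other"]
        src = np.array([[1.0, 1.0, 5.0]])
        tgt = np.array([[1.5, 2.5, 9.0]])
        out = transition_score(src, tgt, {"s": ["m1", "m2"]}, gene_ids=genes)
        assert out["s"][0] == pytest.approx(1.0)

    def test_linearity_and_antisymmetry(self, rng):
        genes = [f"g{i}" for i in range(5)]
        src = rng.random((3, 5))
        tgt = rng.random((3, 5))
        sets = {"s": genes[:4]}
        fwd = transition_score(src, tgt, sets, gene_ids=genes)
        rev = transition_score(tgt, src, sets, gene_ids=genes)
        np.testing.assert_allclose(fwd["s"], -rev["s"])
        shifted = transition_score(src, tgt + 0.7, sets, gene_ids=genes)
        np.testing.assert_allclose(shifted["s"], fwd["s"] + 0.7)

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValidationError):
            transition_score(
                np.ones((1, 2)), np.ones((1, 2)), {"s": ["nope"]}, gene_ids=["a", "b"]
            )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            transition_score(
                np.ones((1, 2)), np.ones((1, 2)), {"s": []}, gene_ids=["a", "b"]
            )


class TestPredictionScore:
    def test_singleton_set_equals_likelihood(self):
        probs = np.array([[0.2, 0.4, 0.4]])
        out = prediction_score(probs, ["a", "b", "c"], {"s": ["b"]})
        assert out["s"][0] == pytest.approx(0.4)

    def test_mean_of_members(self):
        probs = np.array([[0.2, 0.4, 0.4]])
        out = prediction_score(probs, ["a", "b", "c"], {"s": ["a", "b"]})
        assert out["s"][0] == pytest.approx(0.3)

    def test_bounded_in_unit_interval(self, rng):
        probs = rng.dirichlet(np.ones(6), size=20)
        cands = [f"g{i}" for i in range(6)]
        out = prediction_score(probs, cands, {"s": cands[:4]})
        assert ((out["s"] >= 0) & (out["s"] <= 1)).all()

    def test_missing_member_rejected(self):
        with pytest.raises(ValidationError, match="zz"):
            prediction_score(np.ones((1, 2)) / 2, ["a", "b"], {"s": ["zz"]})


class TestDgeBaseline:
    def _group(self, rng, n, genes, shift=None):
        counts = rng.poisson(5, size=(n, len(genes)))
        if shift is not None:
            counts[:, shift] += 60
        counts[counts.sum(axis=1) == 0, 0] = 1
        return CountMatrix([f"c{i}{shift}" for i in range(n)], genes, counts)

    def test_identical_groups_yield_empty_rankings(self, rng):
        # single target cluster vs the same cells as reference: exact null
        genes = [f"g{i}" for i in range(25)]
        counts = rng.poisson(3, size=(60, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        src = CountMatrix([f"s{i}" for i in range(60)], genes, counts)
        tgt = CountMatrix([f"t{i}" for i in range(60)], genes, counts.copy())
        rankings, clusters = dge_baseline_ranking(
            src, tgt, n_clusters=(1, 1), seed=0
        )
        assert all(len(t) == 0 for t in rankings.values())

    def test_strongly_shifted_gene_ranks_first(self, rng):
        genes = [f"g{i}" for i in range(25)]
        src = self._group(rng, 160, genes)
        tgt = self._group(rng, 160, genes, shift=7)
        rankings, clusters = dge_baseline_ranking(src, tgt, n_clusters=(2, 5), seed=0)
        for table in rankings.values():
            assert len(table) > 0
            assert (table["qval"] <= 0.05).all()  # only significant genes listed
        ranks = dge_candidate_ranks(
            rankings, clusters, ["g7"] * len(clusters), ["g3", "g7", "g11"]
        )
        assert np.all(ranks == 1)

    def test_empty_group_rejected(self, rng):
        genes = ["a", "b"]
        grp = CountMatrix(["c1"], genes, np.array([[1, 2]]))
        empty = CountMatrix([], genes, np.empty((0, 2), dtype=int))
        with pytest.raises(ValidationError):
            dge_baseline_ranking(grp, empty)
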