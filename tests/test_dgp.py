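import dataclasses

import numpy as np
import pytest

from drivergraph import (
    FinetuneOptions,
    LikelihoodVector,
    Pair,
    PairedDataset,
    ablation_predict,
    driver_loss,
    finetune,
    init_cmm_params,
    predict_likelihoods,
    rank_candidates,
)
from drivergraph.data_core import ValidationError
from drivergraph.dgp import fit_no_dgp, init_dgp_params
from drivergraph.synthetic_data import SimConfig, build_pair_dataset


@pytest.fixture(scope="module")
def tiny_paired():
    cfg = SimConfig(
        n_genes=40,
        n_states=2,
        n_drivers=4,
        cells_per_pert=6,
        controls_per_state=10,
        graph_density=0.06,
        driver_min_outdegree=2,
        seed=9,
    )
    return build_pair_dataset(cfg, split="in_domain")


@pytest.fixture(scope="module")
def tiny_train_config():
    from drivergraph import ModelConfig

    return ModelConfig(
        H=8,
        n_layers=1,
        n_heads=2,
        coordinate_dim=16,
        d_max=4,
        max_degree_bucket=8,
        dgp_hidden=16,
        dtype="float64",
    )


class TestDriverLoss:
    def test_uniform_logits_give_ln_k(self):
        assert driver_loss(np.zeros(4), 0) == pytest.approx(np.log(4), abs=1e-12)
        assert driver_loss(np.full(7, 3.3), 2) == pytest.approx(np.log(7), abs=1e-12)

    def test_confident_correct_logit_drives_loss_to_zero(self):
        logits = np.zeros(5)
        logits[1] = 50.0
        assert driver_loss(logits, 1) < 1e-12

    def test_hand_computed_value(self):
        # softmax of (1, 0, -1), true class 0
        assert driver_loss(np.array([1.0, 0.0, -1.0]), 0) == pytest.approx(
            0.4076, abs=1e-4
        )

    def test_label_out_of_range(self):
        with pytest.raises(ValidationError):
            driver_loss(np.zeros(3), 3)


class TestRankCandidates:
    def test_direct_sort(self):
        lv = LikelihoodVector(np.array([0.5, 0.3, 0.2]), ["a", "b", "c"])
        ranks = rank_candidates(lv)
        np.testing.assert_array_equal(ranks, [1, 2, 3])
        assert ranks[1] == 2  # true gene at index 1 has rank 2

    def test_tie_break_by_gene_index(self):
        lv = LikelihoodVector(np.full(4, 0.25), list("abcd"))
        np.testing.assert_array_equal(rank_candidates(lv), [1, 2, 3, 4])

    def test_always_a_permutation(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(8))
            ranks = rank_candidates(LikelihoodVector(p, [str(i) for i in range(8)]))
            assert sorted(ranks) == list(range(1, 9))


class TestPairedDataset:
    def test_leakage_guard(self):
        pairs = [
            Pair("s", "t", "gA", split="train"),
            Pair("s", "t", "gA", split="test"),
            Pair("s2", "t2", "gB", split="train"),
        ]
        with pytest.raises(ValidationError, match="both train and test"):
            PairedDataset(pairs)

    def test_driver_outside_candidates(self):
        with pytest.raises(ValidationError, match="candidate"):
            PairedDataset(
                [Pair("s", "t", "gZ", split="test")], candidate_genes=["gA", "gB"]
            )


class TestPredictLikelihoods:
    def test_normalization_and_uniform_at_zero_head(
        self, tiny_paired, tiny_train_config
    ):
        data = tiny_paired
        cfg = tiny_train_config
        cmm = init_cmm_params(data.counts.n_genes, cfg, 0)
        dgp = init_dgp_params(
            2 * cfg.coordinate_dim, data.dataset.candidate_genes, cfg, 1
        )
        src = data.counts.counts[0]
        tgt = data.counts.counts[-1]
        lv = predict_likelihoods(src, tgt, data.graph, cmm, dgp, cfg)
        assert abs(lv.probabilities.sum() - 1) < 1e-6
        # zeroed output layer -> exactly uniform
        dgp.arrays["W2"][:] = 0.0
        dgp.arrays["b2"][:] = 0.0
        lv = predict_likelihoods(src, tgt, data.graph, cmm, dgp, cfg)
        np.testing.assert_allclose(lv.probabilities, 1 / data.dataset.K, atol=1e-12)

    def test_swapping_src_tgt_changes_output(self, tiny_paired, tiny_train_config):
        data = tiny_paired
        cfg = tiny_train_config
        cmm = init_cmm_params(data.counts.n_genes, cfg, 0)
        dgp = init_dgp_params(
            2 * cfg.coordinate_dim, data.dataset.candidate_genes, cfg, 1
        )
        src = data.counts.counts[0]
        tgt = data.counts.counts[-1]
        a = predict_likelihoods(src, tgt, data.graph, cmm, dgp, cfg)
        b = predict_likelihoods(tgt, src, data.graph, cmm, dgp, cfg)
        assert not np.allclose(a.probabilities, b.probabilities)


class TestFinetune:
    def test_seeded_determinism(self, tiny_paired, tiny_train_config):
        data = tiny_paired
        opts = FinetuneOptions(epochs=1, batch_size=8, seed=5)
        r1 = finetune(
            data.dataset, data.counts, data.graph, None, tiny_train_config, opts
        )
        r2 = finetune(
            data.dataset, data.counts, data.graph, None, tiny_train_config, opts
        )
        assert dataclasses.asdict(r1[2]) == dataclasses.asdict(r2[2])
        for k in r1[0].arrays:
            np.testing.assert_array_equal(r1[0].arrays[k], r2[0].arrays[k])

    def test_freeze_cmm_leaves_encoder_untouched(self, tiny_paired, tiny_train_config):
        data = tiny_paired
        init = init_cmm_params(data.counts.n_genes, tiny_train_config, 3)
        opts = FinetuneOptions(epochs=1, batch_size=8, seed=5, freeze_cmm=True)
        cmm, dgp, report = finetune(
            data.dataset, data.counts, data.graph, init, tiny_train_config, opts
        )
        for k in init.arrays:
            np.testing.assert_array_equal(cmm.arrays[k], init.arrays[k])
        assert len(report.train_loss) == 1

    def test_no_cmm_variant_trains_on_expression(self, tiny_paired, tiny_train_config):
        data = tiny_paired
        opts = FinetuneOptions(epochs=2, batch_size=8, seed=5, variant="no_cmm")
        cmm, dgp, report = finetune(
            data.dataset, data.counts, data.graph, None, tiny_train_config, opts
        )
        assert cmm is None
        assert dgp["W1"].shape[0] == 2 * data.counts.n_genes
        assert report.test_top1  # evaluation ran


class TestAblationPredict:
    def test_masked_driver_is_normalized_distribution(
        self, tiny_paired, tiny_train_config
    ):
        data = tiny_paired
        cfg = tiny_train_config
        cmm = init_cmm_params(data.counts.n_genes, cfg, 0)
        dgp = init_dgp_params(2 * cfg.coordinate_dim, data.dataset.candidate_genes, cfg, 1)
        driver = data.counts.gene_index(data.dataset.candidate_genes[0])
        lv = ablation_predict(
            "masked_driver",
            data.counts.counts[0],
            data.counts.counts[-1],
            data.graph,
            cfg,
            cmm_params=cmm,
            dgp_params=dgp,
            driver=driver,
        )
        assert abs(lv.probabilities.sum() - 1) < 1e-6

    def test_no_dgp_decision_function_is_affine(self, tiny_paired, tiny_train_config):
        """The logistic-regression variant must agree with a hand-computed
        softmax of an affine function of the coordinates."""
        data = tiny_paired
        cfg = tiny_train_config
        cmm = init_cmm_params(data.counts.n_genes, cfg, 0)
        model, coords = fit_no_dgp(data.dataset, data.counts, data.graph, cmm, cfg)
        ci = {c: i for i, c in enumerate(data.counts.cell_ids)}
        p = data.dataset.split_pairs("train")[0]
        X = np.concatenate([coords[ci[p.source_id]], coords[ci[p.target_id]]])[None, :]
        z = (X @ model.coef_.T + model.intercept_)[0]
        expect = np.exp(z - z.max())
        expect /= expect.sum()
        got = model.predict_proba(X)[0]
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_variant_param_mismatch_rejected(self, tiny_paired, tiny_train_config):
        data = tiny_paired
        with pytest.raises(ValidationError):
            ablation_predict(
                "no_cmm",
                data.counts.counts[0],
                data.counts.counts[1],
                data.graph,
                tiny_train_config,
            )
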