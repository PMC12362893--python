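"""Training pipeline: masking, reconstruction loss, train/predict/cv contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import ordcell.nn as nn
import ordcell.ot as ot
from ordcell import (
    NodeEmbeddingTable,
    SyntheticSpec,
    TrainingConfig,
    ValidationError,
    combined_loss,
    cross_validate,
    load_checkpoint,
    make_fixture_embeddings,
    mask_nodes,
    predict,
    reconstruction_loss,
    save_checkpoint,
    simulate,
    train,
)
from ordcell.graphs import NodeEmbeddingTable, build_cell_graph


def tiny_dataset(seed=3, cells=40, genes=30):
    spec = SyntheticSpec(
        n_states=3,
        cells_per_state=[cells // 2, cells // 4, cells // 4],
        n_genes=genes,
        n_informative_genes=genes // 2,
        drift_per_state=1.5,
        dispersion=0.2,
        seed=seed,
    )
    return simulate(spec)


def tiny_config(**kw):
    base = dict(
        n_hvg=12,
        hidden_dim=8,
        max_epochs=2,
        batch_size=16,
        seed=11,
        lambda_rec=0.1,
        val_fraction=0.15,
        sinkhorn_iters=100,
    )
    base.update(kw)
    return TrainingConfig(**base)


class TestMaskNodes:
    def _graph(self, rng):
        x, _, _ = tiny_dataset()
        return build_cell_graph(x, 0, NodeEmbeddingTable("zeros", 4), seed=1)

    def test_rate_zero_unchanged(self, rng):
        g = self._graph(rng)
        masked, idx = mask_nodes(g, 0.0, 0)
        assert len(idx) == 0
        np.testing.assert_array_equal(masked.node_features, g.node_features)

    def test_floor_arithmetic(self, rng):
        g = self._graph(rng)
        g100 = build_cell_graph(
            tiny_dataset(cells=4, genes=100)[0], 0, NodeEmbeddingTable("one_hot", 100), seed=1
        )
        _, idx = mask_nodes(g100, 0.15, 0)
        assert len(idx) == 15

    def test_same_seed_same_mask(self, rng):
        g = self._graph(rng)
        _, a = mask_nodes(g, 0.3, 5)
        _, b = mask_nodes(g, 0.3, 5)
        np.testing.assert_array_equal(a, b)

    def test_masked_rows_zeroed_targets_kept(self, rng):
        g = build_cell_graph(
            tiny_dataset(cells=4, genes=20)[0], 1, NodeEmbeddingTable("one_hot", 20), seed=1
        )
        masked, idx = mask_nodes(g, 0.25, 2)
        np.testing.assert_array_equal(masked.node_features[idx], 0.0)
        keep = np.setdiff1d(np.arange(20), idx)
        np.testing.assert_array_equal(masked.node_features[keep], g.node_features[keep])

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            mask_nodes(self._graph(rng), 1.0, 0)


class TestReconstructionLoss:
    def test_identity_near_zero(self, rng):
        P = rng.normal(size=(10, 6))
        assert reconstruction_loss(P, P) <= 1e-3

    def test_translation_gives_shift_norm(self, rng):
        P = rng.normal(size=(12, 5))
        c = np.array([1.0, -2.0, 0.0, 0.5, 1.5])
        assert reconstruction_loss(P, P + c) == pytest.approx(np.linalg.norm(c), rel=0.02)

    def test_matches_exact_transport_oracle(self, rng):
        for _ in range(3):
            P = rng.normal(size=(10, 2))
            Q = P + rng.normal(scale=0.5, size=(10, 2))
            cost = ot.pairwise_distances(P, Q)
            r, c = linear_sum_assignment(cost)
            exact = cost[r, c].mean()
            assert reconstruction_loss(P, Q, eps=0.005, n_iter=3000) == pytest.approx(
                exact, rel=0.02
            )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)))

    def test_empty_is_zero(self):
        assert reconstruction_loss(np.zeros((0, 3)), np.zeros((0, 3))) == 0.0


class TestCombinedLoss:
    def test_rec_weight_zero_reduces_to_ordinal(self):
        cfg = TrainingConfig(lambda_ord=1.0, lambda_rec=0.0)
        assert combined_loss(0.7, 123.0, cfg) == pytest.approx(0.7)

    def test_weighted_sum(self):
        cfg = TrainingConfig(lambda_ord=1.0, lambda_rec=1.0)
        assert combined_loss(0.4, 0.6, cfg) == pytest.approx(1.0)

    def test_gradient_is_weighted_sum_of_gradients(self, rng):
        # d(l1*ord + l2*rec)/dtheta = l1*d(ord) + l2*d(rec) on a shared tensor
        z = nn.Tensor(rng.normal(size=(4, 2)))
        y = np.array([1, 2, 3, 1])
        P = rng.normal(size=(4, 2))
        l1, l2 = 0.7, 0.3

        t_ord = nn.ordinal_masked_bce(z, y, 3)
        t_ord.backward()
        g_ord = z.grad.copy()
        z.grad = None
        z2 = nn.Tensor(z.data)
        t_rec = nn.wasserstein_loss(z2, P, eps=0.02)
        t_rec.backward()
        g_rec = z2.grad.copy()

        z3 = nn.Tensor(z.data)
        total = nn.add(
            nn.scale(nn.ordinal_masked_bce(z3, y, 3), l1),
            nn.scale(nn.wasserstein_loss(z3, P, eps=0.02), l2),
        )
        total.backward()
        np.testing.assert_allclose(z3.grad, l1 * g_ord + l2 * g_rec, atol=1e-10)


class TestTrain:
    def test_zero_epochs_returns_initial_params_empty_log(self):
        x, labels, _ = tiny_dataset()
        emb = NodeEmbeddingTable("zeros", 4)
        ckpt, log = train(x, labels, emb, tiny_config(max_epochs=0))
        assert log == []
        assert set(ckpt) >= {"state", "config", "gene_ids", "states"}

    def test_training_reduces_loss(self):
        x, labels, _ = tiny_dataset(cells=60)
        emb = NodeEmbeddingTable("zeros", 4)
        ckpt, log = train(x, labels, emb, tiny_config(max_epochs=4, val_fraction=0.0, lambda_rec=0.0))
        assert log[-1]["train_ord"] < log[0]["train_ord"]

    def test_missing_state_errors(self):
        x, labels, _ = tiny_dataset()
        labels.states.append("ghost_state")
        emb = NodeEmbeddingTable("zeros", 4)
        with pytest.raises(ValidationError, match="no training cells"):
            train(x, labels, emb, tiny_config())

    def test_log_records_have_expected_fields(self):
        x, labels, _ = tiny_dataset()
        emb = NodeEmbeddingTable("zeros", 4)
        _, log = train(x, labels, emb, tiny_config(max_epochs=1))
        assert {"epoch", "train_ord", "train_rec", "train_loss", "val_ord", "val_acc"} <= set(log[0])


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        x, labels, truth = tiny_dataset(cells=60)
        emb = make_fixture_embeddings(x.gene_ids, dim=8, seed=0)
        ckpt, log = train(x, labels, emb, tiny_config(max_epochs=2))
        return x, labels, ckpt

    def test_deterministic(self, trained):
        x, labels, ckpt = trained
        a = predict(x, ckpt)
        b = predict(x, ckpt)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.embeddings, b.embeddings)

    def test_gene_permutation_invariance(self, trained):
        x, labels, ckpt = trained
        rng = np.random.default_rng(0)
        perm = rng.permutation(x.n_genes)
        xp = x.subset_genes(perm)
        a = predict(x, ckpt)
        b = predict(xp, ckpt)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_genes_imputed_with_warning(self, trained):
        x, labels, ckpt = trained
        keep = np.arange(x.n_genes - 2)
        with pytest.warns(UserWarning, match="imputing zero"):
            out = predict(x.subset_genes(keep), ckpt)
        assert len(out.table) == x.n_cells

    def test_low_overlap_hard_error(self, trained):
        x, labels, ckpt = trained
        n_model = len(ckpt["gene_ids"])
        overlap_cols = [x.gene_ids.index(g) for g in ckpt["gene_ids"][: n_model // 3]]
        with pytest.raises(ValidationError, match="reference"):
            predict(x.subset_genes(np.array(overlap_cols)), ckpt)

    def test_output_columns(self, trained):
        x, labels, ckpt = trained
        out = predict(x, ckpt)
        assert {"cell_id", "predicted_state", "q"} <= set(out.table.columns)
        sigma_cols = [c for c in out.table.columns if c.startswith("p_beyond_")]
        mass_cols = [c for c in out.table.columns if c.startswith("mass_")]
        assert len(sigma_cols) == labels.n_states - 1
        assert len(mass_cols) == labels.n_states
        np.testing.assert_allclose(out.table[mass_cols].sum(axis=1), 1.0, atol=1e-8)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        x, labels, ckpt = trained
        path = tmp_path / "model.npz"
        save_checkpoint(ckpt, path)
        back = load_checkpoint(path)
        a = predict(x, ckpt)
        b = predict(x, back)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestCrossValidate:
    def test_structure_and_partition(self):
        x, labels, _ = tiny_dataset(cells=60)
        emb = NodeEmbeddingTable("zeros", 4)
        res = cross_validate(x, labels, emb, tiny_config(max_epochs=1, lambda_rec=0.0), folds=2, repeats=1)
        assert len(res.folds) == 2
        assert res.folds["n_test"].sum() == x.n_cells
        # mean equals the arithmetic mean of per-fold accuracies
        assert res.mean_accuracy == pytest.approx(res.folds["accuracy"].mean())
        assert "±" in res.summary()
        # confusion matrices count every test cell exactly once
        assert sum(c.sum() for c in res.confusions) == x.n_cells
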