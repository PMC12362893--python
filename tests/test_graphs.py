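"""Per-cell graph construction: noise, log-ratios, RBF features, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordcell import (
    NodeEmbeddingTable,
    RbfBank,
    add_count_noise,
    build_cell_graph,
    logratio_matrix,
    prune_edges,
    rbf_featurize,
    read_embedding_table,
)
from ordcell.io_qc import ExpressionMatrix

positive_rows = st.lists(
    st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=12
)


class TestAddCountNoise:
    def test_zero_vector_sd_zero_gives_constant_mean(self):
        out = add_count_noise(np.zeros(7), noise_mean=0.5, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(out, 0.5)

    def test_same_seed_reproducible(self):
        row = np.arange(10)
        a = add_count_noise(row, seed=42)
        b = add_count_noise(row, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_noise_mean_monte_carlo(self):
        # mean of (noisy - raw) over 1e5 entries ~ 0.5 within 3 standard errors
        n, sd = 100_000, 0.1
        raw = np.zeros(n)
        delta = add_count_noise(raw, noise_mean=0.5, noise_sd=sd, seed=7) - raw
        se = sd / np.sqrt(n)
        assert abs(delta.mean() - 0.5) < 3 * se

    def test_output_strictly_positive(self):
        out = add_count_noise(np.zeros(1000), noise_mean=0.5, noise_sd=5.0, seed=1)
        assert np.all(out > 0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            add_count_noise(np.ones(3), noise_mean=0.0)


class TestLogratioMatrix:
    def test_closed_form_two_genes(self):
        L = logratio_matrix(np.array([np.e, 1.0]))
        np.testing.assert_allclose(L, [[0.0, 1.0], [-1.0, 0.0]], atol=1e-12)

    @given(positive_rows)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_zero_diagonal(self, row):
        L = logratio_matrix(np.array(row))
        np.testing.assert_allclose(L, -L.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(L), 0.0, atol=1e-12)

    def test_matches_elementwise_brute_force(self, rng):
        row = rng.uniform(0.1, 50.0, 5)
        L = logratio_matrix(row)
        for j in range(5):
            for k in range(5):
                assert L[j, k] == pytest.approx(np.log(row[j]) - np.log(row[k]))

    @given(positive_rows, st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, row, c):
        # compositional property: rescaling the whole row changes nothing
        row = np.array(row)
        np.testing.assert_allclose(
            logratio_matrix(row), logratio_matrix(c * row), atol=1e-8
        )

    def test_nonpositive_entry_rejected(self):
        with pytest.raises(ValueError):
            logratio_matrix(np.array([1.0, 0.0]))


class TestRbfFeaturize:
    def test_at_center_is_one(self):
        bank = RbfBank()
        for i, c in enumerate(bank.centers):
            assert rbf_featurize(c, bank)[i] == pytest.approx(1.0)

    def test_one_width_away_is_exp_minus_one(self):
        bank = RbfBank(np.array([-1.0, 2.0]), width_r=0.7)
        out = rbf_featurize(2.0 + 0.7, bank)
        assert out[1] == pytest.approx(np.exp(-1.0))

    def test_matches_scalar_recomputation(self):
        bank = RbfBank(np.linspace(-6, 6, 7), width_r=2.0)
        out = rbf_featurize(0.0, bank)
        expected = [np.exp(-((0.0 - c) ** 2) / 4.0) for c in bank.centers]
        np.testing.assert_allclose(out, expected)

    def test_components_in_unit_interval(self):
        bank = RbfBank()
        out = rbf_featurize(np.linspace(-10, 10, 101), bank)
        assert np.all(out > 0) and np.all(out <= 1.0)

    def test_default_widths_half_nearest_gap(self):
        bank = RbfBank(np.array([0.0, 1.0, 4.0]))
        np.testing.assert_allclose(bank.widths, [0.5, 0.5, 1.5])

    def test_non_increasing_centers_rejected(self):
        with pytest.raises(ValueError):
            RbfBank(np.array([0.0, 0.0, 1.0]))


class TestPruneEdges:
    def test_out_degree_16_when_enough_genes(self, rng):
        L = logratio_matrix(rng.uniform(0.1, 10, 17))
        edges = prune_edges(L)
        src, deg = np.unique(edges[:, 0], return_counts=True)
        assert len(src) == 17 and np.all(deg == 16)

    def test_small_graph_keeps_all_neighbors(self, rng):
        L = logratio_matrix(rng.uniform(0.1, 10, 5))
        edges = prune_edges(L)
        src, deg = np.unique(edges[:, 0], return_counts=True)
        assert np.all(deg == 4)
        assert not np.any(edges[:, 0] == edges[:, 1])

    def test_matches_full_sort_oracle(self, rng):
        L = logratio_matrix(rng.uniform(0.1, 100, 30))
        edges = prune_edges(L, k_top=8, k_bottom=8)
        for j in range(30):
            targets = set(edges[edges[:, 0] == j, 1])
            others = [k for k in range(30) if k != j]
            by_value = sorted(others, key=lambda k: -L[j, k])
            expected = set(by_value[:8]) | set(by_value[-8:])
            assert targets == expected

    def test_no_self_edges(self, rng):
        L = logratio_matrix(rng.uniform(0.1, 10, 20))
        edges = prune_edges(L)
        assert not np.any(edges[:, 0] == edges[:, 1])

    def test_degenerate_constant_row_deduplicates(self):
        L = np.zeros((20, 20))
        edges = prune_edges(L)
        for j in range(20):
            targets = edges[edges[:, 0] == j, 1]
            assert len(targets) == len(set(targets))


class TestBuildCellGraph:
    def _matrix(self, rng, m=20):
        counts = rng.poisson(4.0, size=(3, m))
        return ExpressionMatrix(
            counts, [f"c{i}" for i in range(3)], [f"g{j:02d}" for j in range(m)]
        )

    def test_one_hot_nodes_are_identity(self, rng):
        x = self._matrix(rng)
        g = build_cell_graph(x, 0, NodeEmbeddingTable("one_hot", 20), seed=0)
        np.testing.assert_array_equal(g.node_features, np.eye(20))

    def test_same_seed_bit_identical(self, rng):
        x = self._matrix(rng)
        emb = NodeEmbeddingTable("zeros", 8)
        a = build_cell_graph(x, 1, emb, seed=9)
        b = build_cell_graph(x, 1, emb, seed=9)
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.edge_features, b.edge_features)
        np.testing.assert_array_equal(a.edge_logratio, b.edge_logratio)

    def test_edge_features_recompute_from_logratios(self, rng):
        x = self._matrix(rng, m=10)
        bank = RbfBank()
        g = build_cell_graph(x, 2, NodeEmbeddingTable("zeros", 4), bank=bank, seed=3)
        np.testing.assert_allclose(
            g.edge_features, rbf_featurize(g.edge_logratio, bank)
        )

    def test_antisymmetry_of_surviving_reciprocal_edges(self, rng):
        x = self._matrix(rng, m=12)
        g = build_cell_graph(x, 0, NodeEmbeddingTable("zeros", 4), seed=5)
        ratio = {(s, t): r for (s, t), r in zip(map(tuple, g.edges), g.edge_logratio)}
        for (s, t), r in ratio.items():
            if (t, s) in ratio:
                assert ratio[(t, s)] == pytest.approx(-r, abs=1e-9)

    def test_missing_embedding_gene_zero_filled(self, rng):
        x = self._matrix(rng, m=5)
        table = NodeEmbeddingTable(
            "distributed", 3, {g: np.ones(3) for g in x.gene_ids[:-1]}
        )
        g = build_cell_graph(x, 0, table, seed=0)
        np.testing.assert_array_equal(g.node_features[-1], np.zeros(3))

    def test_graph_cache_round_trip(self, tmp_path, rng):
        from ordcell.graphs import load_cell_graph, save_cell_graph

        x = self._matrix(rng, m=12)
        g = build_cell_graph(x, 0, NodeEmbeddingTable("one_hot", 12), seed=4)
        path = tmp_path / "graph.npz"
        save_cell_graph(g, path)
        back = load_cell_graph(path)
        assert back.gene_ids == g.gene_ids
        np.testing.assert_array_equal(back.edges, g.edges)
        np.testing.assert_array_equal(back.edge_features, g.edge_features)
        np.testing.assert_array_equal(back.node_features, g.node_features)

    def test_embedding_table_round_trip(self, tmp_path, rng):
        vecs = {f"g{i}": rng.normal(size=4) for i in range(6)}
        lines = [
            "\t".join([g] + [f"{v:.8f}" for v in vec]) for g, vec in vecs.items()
        ]
        path = tmp_path / "emb.tsv"
        path.write_text("\n".join(lines) + "\n")
        table = read_embedding_table(path)
        assert table.dim == 4
        for g, vec in vecs.items():
            np.testing.assert_allclose(table.vectors[g], vec, atol=1e-8)
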