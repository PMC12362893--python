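"""Dual-layer message-passing encoder-decoder over per-cell gene graphs.

The encoder runs three rounds of message passing. In each round, every edge
computes a message from the concatenation of its source node state, target
node state and edge state through a three-layer perceptron; incoming messages
are aggregated per node, reweighted by a neighborhood perceptron, and added
residually (layer norm + dropout). A second perceptron of like structure then
recomputes edge messages and updates the edge states residually. The decoder
is a single message round that updates nodes only and projects them back to
the input embedding dimension, producing the reconstructed gene
representations used by the reconstruction loss.

"Dual-layer" refers to the two information layers carried by one graph:
expression-derived log-ratio edge features, and prior co-expression knowledge
in the node embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from . import nn
from .graphs import CellGraph

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` is the shared width all node/edge states are aligned to;
    the edge-message perceptrons use hidden sizes (3h, h, h), which at the
    default h=128 gives the (384, 128, 128) stack. ``n_rounds`` is fixed at 3
    by design; overriding it is logged as a deviation.
    """

    hidden_dim: int = 128
    n_rounds: int = 3
    dropout: float = 0.10
    aggregation: str = "sum"  # "sum" | "softmax"
    head: str = "ordinal"  # "ordinal" | "softmax" (ablation)
    dtype: str = "float64"  # "float32" halves memory traffic for training


class GraphBatch:
    """A batch of cell graphs flattened into one disjoint union graph."""

    def __init__(self, graphs: list[CellGraph], dtype=None):
        dtype = np.dtype(dtype) if dtype is not None else np.float64
        self.n_graphs = len(graphs)
        node_offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        self.n_nodes = int(node_offsets[-1])
        self.node_features = np.concatenate(
            [g.node_features for g in graphs]
        ).astype(dtype, copy=False)
        self.edge_features = np.concatenate(
            [g.edge_features for g in graphs]
        ).astype(dtype, copy=False)
        self.edges = np.concatenate(
            [g.edges + off for g, off in zip(graphs, node_offsets[:-1])]
        )
        self.n_edges = len(self.edges)
        e_idx = np.arange(self.n_edges)
        # incoming incidence: aggregates edge rows onto their target node
        self.incidence_in = sparse.csr_matrix(
            (np.ones(self.n_edges, dtype=dtype), (self.edges[:, 1], e_idx)),
            shape=(self.n_nodes, self.n_edges),
        )
        # node->edge selection transposes for fast gather backward passes
        self.scatter_src = sparse.csr_matrix(
            (np.ones(self.n_edges, dtype=dtype), (self.edges[:, 0], e_idx)),
            shape=(self.n_nodes, self.n_edges),
        )
        self.scatter_tgt = self.incidence_in
        graph_of_node = np.concatenate(
            [np.full(g.n_nodes, i) for i, g in enumerate(graphs)]
        )
        weights = np.concatenate(
            [np.full(g.n_nodes, 1.0 / g.n_nodes, dtype=dtype) for g in graphs]
        )
        self.pool = sparse.csr_matrix(
            (weights, (graph_of_node, np.arange(self.n_nodes))),
            shape=(self.n_graphs, self.n_nodes),
        )
        self.node_slices = [
            slice(int(a), int(b)) for a, b in zip(node_offsets[:-1], node_offsets[1:])
        ]


@dataclass
class EncodedCell:
    """Node/edge hidden states plus the pooled per-cell embedding."""

    node_states: nn.Tensor
    edge_states: nn.Tensor
    cell_embedding: nn.Tensor


def _as_batch(g: CellGraph | GraphBatch) -> GraphBatch:
    return g if isinstance(g, GraphBatch) else GraphBatch([g])


class EdgeMessageMLP:
    """Three-layer perceptron on concat(source node, target node, edge state).

    The first layer is evaluated as three split projections — the node terms
    are computed once per node and gathered onto edges — which is algebraically
    identical to a dense layer on the concatenation but avoids redundant
    per-edge matmuls (each node feeds ~16 edges).
    """

    def __init__(self, h: int, rng: np.random.Generator, name: str = ""):
        self.w_src = nn.Linear(h, 3 * h, rng, f"{name}.src")
        self.w_tgt = nn.Linear(h, 3 * h, rng, f"{name}.tgt")
        self.w_edge = nn.Linear(h, 3 * h, rng, f"{name}.edge")
        self.hidden = nn.Linear(3 * h, h, rng, f"{name}.hidden")
        self.out = nn.Linear(h, h, rng, f"{name}.out")

    def __call__(self, nodes, edges, src, tgt, s_src=None, s_tgt=None):
        x = nn.add(
            nn.add(
                nn.gather_rows(self.w_src(nodes), src, scatter_t=s_src),
                nn.gather_rows(self.w_tgt(nodes), tgt, scatter_t=s_tgt),
            ),
            self.w_edge(edges),
        )
        return self.out(nn.relu(self.hidden(nn.relu(x))))

    def parameters(self) -> list[nn.Tensor]:
        return [
            p
            for m in (self.w_src, self.w_tgt, self.w_edge, self.hidden, self.out)
            for p in m.parameters()
        ]


class ModelParams:
    """All trainable weights of the encoder, decoder and classification head."""

    def __init__(
        self,
        cfg: ModelConfig,
        node_dim: int,
        n_kernels: int,
        n_states: int,
        rng: np.random.Generator,
    ):
        if cfg.n_rounds != 3:
            logger.warning(
                "encoder depth %d deviates from the designed 3 rounds", cfg.n_rounds
            )
        self.cfg = cfg
        self.node_dim = node_dim
        self.n_kernels = n_kernels
        self.n_states = n_states
        h = cfg.hidden_dim
        self._modules: dict[str, object] = {}

        def reg(name, module):
            self._modules[name] = module
            return module

        self.node_align = reg("node_align", nn.Linear(node_dim, h, rng, "node_align"))
        self.edge_align = reg("edge_align", nn.Linear(n_kernels, h, rng, "edge_align"))
        self.edge_message_mlp_enc = reg(
            "edge_message_mlp_enc", EdgeMessageMLP(h, rng, "edge_message_mlp_enc")
        )
        self.neighborhood_perceptron = reg(
            "neighborhood_perceptron", nn.Linear(h, h, rng, "neighborhood_perceptron")
        )
        self.ln_node = reg("ln_node", nn.LayerNormModule(h, "ln_node"))
        self.edge_update_mlp_enc = reg(
            "edge_update_mlp_enc", EdgeMessageMLP(h, rng, "edge_update_mlp_enc")
        )
        self.ln_edge = reg("ln_edge", nn.LayerNormModule(h, "ln_edge"))
        self.decoder_message_mlp = reg(
            "decoder_message_mlp", EdgeMessageMLP(h, rng, "decoder_message_mlp")
        )
        self.ln_dec = reg("ln_dec", nn.LayerNormModule(h, "ln_dec"))
        self.node_reconstructor = reg(
            "node_reconstructor", nn.Linear(h, node_dim, rng, "node_reconstructor")
        )
        n_out = n_states - 1 if cfg.head == "ordinal" else n_states
        self.classifier_head = reg(
            "classifier_head", nn.Linear(h, n_out, rng, "classifier_head")
        )
        if cfg.aggregation == "softmax":
            self.attention = reg("attention", nn.Linear(h, 1, rng, "attention"))
        elif cfg.aggregation != "sum":
            raise ValueError(f"unknown aggregation {cfg.aggregation!r}")
        if cfg.dtype != "float64":
            for p in self.parameters():
                p.data = p.data.astype(cfg.dtype)

    def parameters(self) -> list[nn.Tensor]:
        return [p for m in self._modules.values() for p in m.parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            if state[p.name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: "
                    f"{state[p.name].shape} vs {p.data.shape}"
                )
            p.data = state[p.name].astype(p.data.dtype)


def _aggregate(msg: nn.Tensor, batch: GraphBatch, p: ModelParams) -> nn.Tensor:
    """Aggregate per-edge messages onto their target nodes."""
    if p.cfg.aggregation == "sum":
        return nn.spmm(batch.incidence_in, msg)
    # softmax attention over each node's incoming edges
    tgt = batch.edges[:, 1]
    score = p.attention(msg)  # (E, 1)
    shift = np.full(batch.n_nodes, -np.inf)
    np.maximum.at(shift, tgt, score.data[:, 0])
    exp_s = nn.exp(
        nn.add(score, nn.Tensor((-shift[tgt][:, None]).astype(score.data.dtype)))
    )
    den = nn.spmm(batch.incidence_in, exp_s)
    alpha = nn.div(exp_s, nn.gather_rows(den, tgt))
    return nn.spmm(batch.incidence_in, nn.mul(msg, alpha))


def align_inputs(g: CellGraph | GraphBatch, p: ModelParams) -> EncodedCell:
    """Project raw node and edge features to the shared hidden width."""
    batch = _as_batch(g)
    if batch.node_features.shape[1] != p.node_dim:
        raise ValueError(
            f"node feature dim {batch.node_features.shape[1]} does not match "
            f"model node_dim {p.node_dim}"
        )
    nodes = p.node_align(nn.Tensor(batch.node_features))
    edges = p.edge_align(nn.Tensor(batch.edge_features))
    pooled = nn.spmm(batch.pool, nodes)
    return EncodedCell(nodes, edges, pooled)


def encoder_round(
    state: EncodedCell,
    g: CellGraph | GraphBatch,
    p: ModelParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> EncodedCell:
    """One round of message passing: update nodes, then edges, residually."""
    batch = _as_batch(g)
    rng = rng or np.random.default_rng(0)
    src, tgt = batch.edges[:, 0], batch.edges[:, 1]
    nodes, edges = state.node_states, state.edge_states

    msg = p.edge_message_mlp_enc(
        nodes, edges, src, tgt, batch.scatter_src, batch.scatter_tgt
    )
    agg = _aggregate(msg, batch, p)
    upd = p.neighborhood_perceptron(agg)
    nodes2 = p.ln_node(
        nn.add(nodes, nn.dropout(upd, p.cfg.dropout, rng, train_mode))
    )

    msg2 = p.edge_update_mlp_enc(
        nodes2, edges, src, tgt, batch.scatter_src, batch.scatter_tgt
    )
    edges2 = p.ln_edge(nn.add(edges, msg2))

    pooled = nn.spmm(batch.pool, nodes2)
    return EncodedCell(nodes2, edges2, pooled)


def encode(
    g: CellGraph | GraphBatch,
    p: ModelParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> EncodedCell:
    """Align inputs, run the fixed number of rounds, mean-pool per cell."""
    batch = _as_batch(g)
    state = align_inputs(batch, p)
    for _ in range(p.cfg.n_rounds):
        state = encoder_round(state, batch, p, train_mode=train_mode, rng=rng)
    return state


def decode(
    enc: EncodedCell,
    g: CellGraph | GraphBatch,
    p: ModelParams,
    rows: np.ndarray | None = None,
) -> nn.Tensor:
    """One node-only message round, then project back to the embedding dim.

    Edge states are read but never written; the result Q has one row per node
    in the original node-embedding dimension. When ``rows`` (sorted node
    indices) is given, only those nodes are decoded — the masked-modeling
    training path, which skips messages along edges that do not end on a
    reconstructed node.
    """
    batch = _as_batch(g)
    if rows is None:
        src, tgt = batch.edges[:, 0], batch.edges[:, 1]
        msg = p.decoder_message_mlp(
            enc.node_states, enc.edge_states, src, tgt,
            batch.scatter_src, batch.scatter_tgt,
        )
        agg = nn.spmm(batch.incidence_in, msg)
        nodes = p.ln_dec(nn.add(enc.node_states, agg))
        return p.node_reconstructor(nodes)

    rows = np.asarray(rows, dtype=np.int64)
    sel = np.flatnonzero(np.isin(batch.edges[:, 1], rows))
    src, tgt = batch.edges[sel, 0], batch.edges[sel, 1]
    msg = p.decoder_message_mlp(
        enc.node_states, nn.gather_rows(enc.edge_states, sel), src, tgt
    )
    pos = np.searchsorted(rows, tgt)
    S = sparse.csr_matrix(
        (np.ones(len(sel), dtype=enc.node_states.data.dtype), (pos, np.arange(len(sel)))),
        shape=(len(rows), len(sel)),
    )
    agg = nn.spmm(S, msg)
    nodes = p.ln_dec(nn.add(nn.gather_rows(enc.node_states, rows), agg))
    return p.node_reconstructor(nodes)


def head_logits(enc: EncodedCell, p: ModelParams) -> nn.Tensor:
    """Classifier logits from the pooled cell embedding.

    (n_states - 1) threshold logits for the ordinal head, n_states class
    logits for the softmax ablation head.
    """
    return p.classifier_head(enc.cell_embedding)
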