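"""Per-cell gene graphs: nodes are genes, edges carry log-ratio features.

One cell's expression vector is turned into a directed graph: every gene is a
node (optionally carrying a prior co-expression embedding), and each gene keeps
edges to the 8 genes with the largest and the 8 with the smallest pairwise
log-ratio against it. The scalar log-ratio on each surviving edge is expanded
into a dense vector by a bank of Gaussian radial basis kernels.

Because log-ratios are invariant to rescaling the whole count vector, the edge
features are compositional: they do not depend on sequencing depth, which is
what makes models trained on one platform transfer to another.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Default kernel centers: log-ratios concentrate near 0, so the grid is
#: denser there while still covering the observed [-6, 6] range.
DEFAULT_RBF_CENTERS = (-6.0, -3.0, -1.5, -0.5, 0.5, 1.5, 3.0, 6.0)

#: Positive floor applied after adding noise so logs are always defined.
NOISE_FLOOR = 1e-6


@dataclass
class RbfBank:
    """A bank of Gaussian radial basis kernels turning a scalar into a vector.

    ``widths`` defaults to half the gap to the nearest neighboring center,
    per kernel; pass ``width_r`` to force one shared spread instead.
    """

    centers: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_RBF_CENTERS))
    width_r: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 1 or len(self.centers) < 1:
            raise ValueError("centers must be a 1-d vector")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.width_r is not None:
            if self.width_r <= 0:
                raise ValueError("width_r must be positive")
            self.widths = np.full(len(self.centers), float(self.width_r))
        else:
            gaps = np.diff(self.centers)
            nearest = np.empty(len(self.centers))
            nearest[0] = gaps[0]
            nearest[-1] = gaps[-1]
            if len(self.centers) > 2:
                nearest[1:-1] = np.minimum(gaps[:-1], gaps[1:])
            self.widths = nearest / 2.0

    @property
    def n_kernels(self) -> int:
        return len(self.centers)


@dataclass
class NodeEmbeddingTable:
    """Gene -> node-vector lookup for the graph's node layer.

    Modes:

    - ``zeros``: no prior information; the network sees expression only.
    - ``one_hot``: gene identity only (dim = number of genes).
    - ``distributed``: dense co-expression embeddings (e.g. 200-d Gene2vec-style
      vectors) loaded from a table.
    """

    mode: str
    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def features_for(self, gene_ids: list[str]) -> np.ndarray:
        """Stack node features for the given genes; shape (n_genes, dim).

        In distributed mode, genes absent from the table get the zero vector
        (with a logged warning).
        """
        m = len(gene_ids)
        if self.mode == "zeros":
            return np.zeros((m, self.dim))
        if self.mode == "one_hot":
            return np.eye(m)
        if self.mode == "distributed":
            out = np.zeros((m, self.dim))
            missing = []
            for i, g in enumerate(gene_ids):
                vec = self.vectors.get(g)
                if vec is None:
                    missing.append(g)
                else:
                    out[i] = vec
            if missing:
                logger.warning(
                    "%d/%d genes missing from embedding table (zero-filled), e.g. %s",
                    len(missing), m, missing[:5],
                )
            return out
        raise ValueError(f"unknown embedding mode {self.mode!r}")

    def node_dim(self, n_genes: int) -> int:
        return n_genes if self.mode == "one_hot" else self.dim


def read_embedding_table(path: str | Path, mode: str = "distributed") -> NodeEmbeddingTable:
    """Read a headerless TSV: column 1 gene symbol, columns 2..d+1 floats."""
    df = pd.read_csv(path, sep=r"\s+", header=None)
    genes = df.iloc[:, 0].astype(str)
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    vectors = {g: mat[i] for i, g in enumerate(genes)}
    return NodeEmbeddingTable(mode=mode, dim=mat.shape[1], vectors=vectors)


@dataclass
class CellGraph:
    """One cell as a pruned directed gene graph."""

    gene_ids: list[str]
    node_features: np.ndarray          # (n_genes, node_dim)
    edges: np.ndarray                  # (n_edges, 2) int: (source, target)
    edge_features: np.ndarray          # (n_edges, n_kernels)
    edge_logratio: np.ndarray          # (n_edges,) raw scalar per edge

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def save_cell_graph(g: CellGraph, path: str | Path) -> None:
    """Cache a CellGraph as a single NPZ bundle."""
    np.savez_compressed(
        path,
        gene_ids=np.array(g.gene_ids),
        node_features=g.node_features,
        edges=g.edges,
        edge_features=g.edge_features,
        edge_logratio=g.edge_logratio,
    )


def load_cell_graph(path: str | Path) -> CellGraph:
    with np.load(path, allow_pickle=False) as z:
        return CellGraph(
            gene_ids=[str(s) for s in z["gene_ids"]],
            node_features=z["node_features"],
            edges=z["edges"],
            edge_features=z["edge_features"],
            edge_logratio=z["edge_logratio"],
        )


def add_count_noise(
    counts_row: np.ndarray,
    noise_mean: float = 0.5,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add Gaussian noise with positive mean so every count is strictly > 0.

    Zero counts dominate single-cell matrices and log(0) is undefined; shifting
    every entry by a draw from N(noise_mean, noise_sd^2) avoids that while
    acting as stochastic regularization. The result is floored at a tiny
    positive value so the log is always defined even for extreme draws.
    """
    if noise_mean <= 0:
        raise ValueError("noise_mean must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = np.asarray(counts_row, dtype=float) + rng.normal(
        noise_mean, noise_sd, size=np.shape(counts_row)
    )
    return np.maximum(noisy, NOISE_FLOOR)


def logratio_matrix(noisy_row: np.ndarray) -> np.ndarray:
    """All pairwise log-ratios of one cell's (strictly positive) expression.

    ``L[j, k] = log(x_j) - log(x_k)`` (natural log); antisymmetric with a zero
    diagonal. Invariant to multiplying the whole row by a constant.
    """
    x = np.asarray(noisy_row, dtype=float)
    if np.any(x <= 0):
        raise ValueError("logratio_matrix requires strictly positive entries")
    lx = np.log(x)
    return lx[:, None] - lx[None, :]


def rbf_featurize(x: float | np.ndarray, bank: RbfBank) -> np.ndarray:
    """Expand scalar log-ratio(s) into Gaussian kernel responses.

    Component k is ``exp(-(x - c_k)^2 / r_k^2)``; each lies in (0, 1] and is
    exactly 1 when x sits on the kernel center.
    """
    x = np.asarray(x, dtype=float)
    return np.exp(-((x[..., None] - bank.centers) ** 2) / bank.widths**2)


def prune_edges(L: np.ndarray, k_top: int = 8, k_bottom: int = 8) -> np.ndarray:
    """Keep, per source gene, edges to the extremes of its log-ratio row.

    For each node j the k_top targets with the largest ``L[j, .]`` and the
    k_bottom with the smallest are kept (outgoing view), excluding the zero
    self-ratio. Ties break by gene index ascending; a target appearing in both
    sets (only possible for degenerate near-constant rows) is emitted once.
    Falls back to all m-1 neighbors when the graph is too small.

    Returns an ``(n_edges, 2)`` integer array of (source, target) pairs.
    """
    m = L.shape[0]
    edges: list[tuple[int, int]] = []
    for j in range(m):
        row = L[j].astype(float).copy()
        if m - 1 <= k_top + k_bottom:
            targets = [k for k in range(m) if k != j]
        else:
            hi = row.copy()
            hi[j] = -np.inf
            # stable argsort on the negated row: largest first, ties by index
            top = np.argsort(-hi, kind="stable")[:k_top]
            lo = row.copy()
            lo[j] = np.inf
            bottom = np.argsort(lo, kind="stable")[:k_bottom]
            targets = list(top) + [t for t in bottom if t not in set(top)]
        edges.extend((j, int(t)) for t in targets)
    return np.array(edges, dtype=np.int64).reshape(-1, 2)


def build_cell_graph(
    x: ExpressionMatrix,
    cell_index: int,
    embeddings: NodeEmbeddingTable,
    bank: RbfBank | None = None,
    seed: int | np.random.Generator = 0,
    noise_mean: float = 0.5,
    noise_sd: float = 0.1,
    k_top: int = 8,
    k_bottom: int = 8,
) -> CellGraph:
    """Compose noise -> log-ratios -> pruning -> RBF features for one cell."""
    if not 0 <= cell_index < x.n_cells:
        raise IndexError(f"cell_index {cell_index} out of range")
    bank = bank or RbfBank()
    noisy = add_count_noise(x.counts[cell_index], noise_mean, noise_sd, seed)
    L = logratio_matrix(noisy)
    edges = prune_edges(L, k_top=k_top, k_bottom=k_bottom)
    ratios = L[edges[:, 0], edges[:, 1]] if len(edges) else np.zeros(0)
    feats = (
        rbf_featurize(ratios, bank) if len(edges) else np.zeros((0, bank.n_kernels))
    )
    node_features = embeddings.features_for(x.gene_ids)
    return CellGraph(
        gene_ids=list(x.gene_ids),
        node_features=node_features,
        edges=edges,
        edge_features=feats,
        edge_logratio=np.asarray(ratios, dtype=float),
    )
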