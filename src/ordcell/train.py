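"""Training loop, combined loss, inference and cross-validation.

The model is trained by minibatch Adam on a weighted sum of two objectives:
the ordinal-regression loss over conditional subsets (primary), and a masked
gene-representation reconstruction loss, an approximate 1-Wasserstein
distance between the original node embeddings of masked genes and the
decoder's reconstructions (auxiliary). Per-cell graphs are rebuilt every
epoch with fresh count noise (stochastic regularization); at inference the
noise seed is fixed so predictions are deterministic.
"""

from __future__ import annotations

import gc
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from . import nn, ot
from .graphs import (
    DEFAULT_RBF_CENTERS,
    CellGraph,
    NodeEmbeddingTable,
    RbfBank,
    add_count_noise,
    logratio_matrix,
    prune_edges,
    rbf_featurize,
)
from .io_qc import ExpressionMatrix, OrdinalStateSet, ValidationError, select_hvgs
from .mpnn import GraphBatch, ModelConfig, ModelParams, decode, encode, head_logits
from .ordinal import cumulative_probabilities, decode_state

_INFERENCE_NOISE_STREAM = 991  # fixed sub-stream tag for inference noise


@dataclass
class TrainingConfig:
    """Everything that controls featurization, architecture and optimization.

    Featurization: ``n_hvg`` genes are kept; count noise N(noise_mean,
    noise_sd^2) makes logs defined; each gene keeps edges to its ``k_top``
    largest and ``k_bottom`` smallest log-ratio partners; RBF centers/width
    control the edge featurization. Optimization: Adam at ``learning_rate``
    with plateau decay (``lr_decay`` every ``lr_decay_patience`` stale
    epochs), minibatches of ``batch_size``, at most ``max_epochs`` epochs
    with early stopping on the held-out split; ``early_stopping_metric``
    selects the best epoch by validation accuracy (default) or validation
    ordinal loss. ``lambda_ord``/``lambda_rec`` weight the two loss terms;
    ``mask_rate`` is the fraction of genes masked for reconstruction.
    """

    batch_size: int = 16
    max_epochs: int = 28
    early_stopping_patience: int = 5
    val_fraction: float = 0.10
    mask_rate: float = 0.15
    lambda_ord: float = 1.0
    lambda_rec: float = 0.1
    learning_rate: float = 1e-3
    seed: int = 0
    threshold: float = 0.5
    n_hvg: int = 600
    noise_mean: float = 0.5
    noise_sd: float = 0.1
    k_top: int = 8
    k_bottom: int = 8
    rbf_centers: tuple = DEFAULT_RBF_CENTERS
    rbf_width: float | None = None
    hidden_dim: int = 128
    n_rounds: int = 3
    dropout: float = 0.10
    aggregation: str = "sum"
    head: str = "ordinal"
    rec_all_nodes: bool = False
    sinkhorn_eps: float = 0.01
    sinkhorn_iters: int = 200
    dtype: str = "float32"
    lr_decay: float = 0.5  # multiplier applied when the early-stopping metric plateaus
    lr_decay_patience: int = 2
    early_stopping_metric: str = "accuracy"  # "accuracy" | "loss"

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            hidden_dim=self.hidden_dim,
            n_rounds=self.n_rounds,
            dropout=self.dropout,
            aggregation=self.aggregation,
            head=self.head,
            dtype=self.dtype,
        )

    def rbf_bank(self) -> RbfBank:
        return RbfBank(np.asarray(self.rbf_centers, dtype=float), self.rbf_width)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rbf_centers"] = list(d["rbf_centers"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "rbf_centers" in d:
            d["rbf_centers"] = tuple(d["rbf_centers"])
        return cls(**d)


def mask_nodes(
    g: CellGraph, mask_rate: float, seed: int | np.random.Generator
) -> tuple[CellGraph, np.ndarray]:
    """Zero out a random floor(mask_rate * n_genes) subset of node rows.

    Returns a shallow copy of the graph with masked node features and the
    masked row indices; the caller keeps the original features as targets.
    """
    if not 0 <= mask_rate < 1:
        raise ValueError("mask_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mask = int(np.floor(mask_rate * g.n_nodes))
    mask = np.sort(rng.choice(g.n_nodes, n_mask, replace=False))
    feats = g.node_features.copy()
    feats[mask] = 0.0
    masked = CellGraph(
        gene_ids=g.gene_ids,
        node_features=feats,
        edges=g.edges,
        edge_features=g.edge_features,
        edge_logratio=g.edge_logratio,
    )
    return masked, mask


def reconstruction_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    eps: float = 0.01,
    n_iter: int = 500,
) -> float:
    """Approximate W1 between original and reconstructed representation rows."""
    P = np.atleast_2d(np.asarray(original, dtype=float))
    Q = np.atleast_2d(np.asarray(reconstructed, dtype=float))
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    if P.shape[0] == 0:
        return 0.0
    return ot.sinkhorn_w1(P, Q, eps=eps, n_iter=n_iter)


def combined_loss(ord_loss: float, rec_loss: float, cfg: TrainingConfig) -> float:
    """Weighted sum lambda_ord * ordinal + lambda_rec * reconstruction."""
    return cfg.lambda_ord * ord_loss + cfg.lambda_rec * rec_loss


# ---------------------------------------------------------------------------
# graph assembly


def _build_graphs(
    counts: np.ndarray,
    gene_ids: list[str],
    node_features: np.ndarray,
    bank: RbfBank,
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> list[CellGraph]:
    graphs = []
    for row in counts:
        noisy = add_count_noise(row, cfg.noise_mean, cfg.noise_sd, rng)
        L = logratio_matrix(noisy)
        edges = prune_edges(L, cfg.k_top, cfg.k_bottom)
        ratios = L[edges[:, 0], edges[:, 1]]
        graphs.append(
            CellGraph(
                gene_ids=gene_ids,
                node_features=node_features,
                edges=edges,
                edge_features=rbf_featurize(ratios, bank),
                edge_logratio=ratios,
            )
        )
    return graphs


def _build_eval_batches(
    counts: np.ndarray,
    gene_ids: list[str],
    node_features: np.ndarray,
    bank: RbfBank,
    cfg: TrainingConfig,
    noise_rng_key: int,
    chunk: int = 64,
) -> list[GraphBatch]:
    """Featurize cells with the fixed inference noise stream, in chunks."""
    rng = np.random.default_rng([cfg.seed % (2**31), noise_rng_key])
    batches = []
    for lo in range(0, len(counts), chunk):
        graphs = _build_graphs(
            counts[lo : lo + chunk], gene_ids, node_features, bank, cfg, rng
        )
        batches.append(GraphBatch(graphs, dtype=cfg.dtype))
    return batches


def _eval_on_batches(
    model: ModelParams, batches: list[GraphBatch]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic forward pass; returns (logits, cell_embeddings)."""
    logits, embs = [], []
    for batch in batches:
        enc = encode(batch, model, train_mode=False)
        logits.append(head_logits(enc, model).data.astype(np.float64))
        embs.append(enc.cell_embedding.data.astype(np.float64))
        del enc
        gc.collect()  # forward graphs hold closure cycles; free them promptly
    return np.concatenate(logits), np.concatenate(embs)


def _forward_eval(
    model: ModelParams,
    counts: np.ndarray,
    gene_ids: list[str],
    node_features: np.ndarray,
    bank: RbfBank,
    cfg: TrainingConfig,
    noise_rng_key: int,
    chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    batches = _build_eval_batches(
        counts, gene_ids, node_features, bank, cfg, noise_rng_key, chunk
    )
    return _eval_on_batches(model, batches)


def _predicted_states(logits: np.ndarray, cfg: TrainingConfig) -> np.ndarray:
    if cfg.head == "ordinal":
        return np.atleast_1d(decode_state(logits, cfg.threshold))
    return logits.argmax(axis=1) + 1


# ---------------------------------------------------------------------------
# training


def _check_labels(y: np.ndarray, n_states: int) -> None:
    present, counts = np.unique(y, return_counts=True)
    if len(present) < 2:
        raise ValidationError("training labels cover fewer than 2 states")
    missing = sorted(set(range(1, n_states + 1)) - set(present.tolist()))
    if missing:
        raise ValidationError(f"states with no training cells: {missing}")
    if np.any(counts < 2):
        warnings.warn("some states have fewer than 2 training cells")


def train(
    x: ExpressionMatrix,
    labels: OrdinalStateSet,
    embeddings: NodeEmbeddingTable,
    cfg: TrainingConfig,
) -> tuple[dict, list[dict]]:
    """Fit the model; returns (checkpoint, per-epoch log).

    The checkpoint bundles all weights, the config, the HVG gene list and the
    state order, plus the node-feature table for those genes, so inference can
    validate and featurize a query on its own.
    """
    y_all = labels.labels_for(x.cell_ids)
    n_states = labels.n_states
    _check_labels(y_all, n_states)

    x = select_hvgs(x, cfg.n_hvg)
    gene_ids = list(x.gene_ids)
    node_features = embeddings.features_for(gene_ids)
    node_dim = node_features.shape[1]
    bank = cfg.rbf_bank()

    master = np.random.default_rng(cfg.seed % (2**31))
    model = ModelParams(
        cfg.model_config(), node_dim, bank.n_kernels, n_states, master
    )
    checkpoint = {
        "state": model.state_dict(),
        "config": cfg.to_dict(),
        "gene_ids": gene_ids,
        "states": list(labels.states),
        "node_features": node_features,
    }
    log: list[dict] = []
    if cfg.max_epochs == 0:
        return checkpoint, log

    # held-out split for early stopping
    idx = np.arange(x.n_cells)
    if cfg.val_fraction > 0 and x.n_cells >= 10:
        strat = y_all if np.min(np.bincount(y_all)[1:]) >= 2 else None
        tr_idx, va_idx = train_test_split(
            idx,
            test_size=cfg.val_fraction,
            random_state=cfg.seed % (2**31),
            stratify=strat,
        )
    else:
        tr_idx, va_idx = idx, np.array([], dtype=int)

    counts_tr, y_tr = x.counts[tr_idx], y_all[tr_idx]
    counts_va, y_va = x.counts[va_idx], y_all[va_idx]

    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    dropout_rng = np.random.default_rng([cfg.seed % (2**31), 7])
    best_val = np.inf
    best_state = model.state_dict()
    patience_left = cfg.early_stopping_patience
    epochs_since_best = 0
    use_rec = cfg.lambda_rec > 0 and (cfg.rec_all_nodes or cfg.mask_rate > 0)
    # validation features use the fixed inference noise stream -> build once
    val_batches = (
        _build_eval_batches(counts_va, gene_ids, node_features, bank, cfg, noise_rng_key=2)
        if len(counts_va)
        else []
    )

    for epoch in range(cfg.max_epochs):
        epoch_rng = np.random.default_rng([cfg.seed % (2**31), 1, epoch])
        order = epoch_rng.permutation(len(counts_tr))
        ord_sum = rec_sum = 0.0
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            graphs = _build_graphs(
                counts_tr[sel], gene_ids, node_features, bank, cfg, epoch_rng
            )
            masks = []
            if use_rec and not cfg.rec_all_nodes:
                masked_graphs = []
                for g in graphs:
                    mg, mask = mask_nodes(g, cfg.mask_rate, epoch_rng)
                    masked_graphs.append(mg)
                    masks.append(mask)
                graphs = masked_graphs
            batch = GraphBatch(graphs, dtype=cfg.dtype)
            enc = encode(batch, model, train_mode=True, rng=dropout_rng)
            logits = head_logits(enc, model)
            if cfg.head == "ordinal":
                loss_ord = nn.ordinal_masked_bce(logits, y_tr[sel], n_states)
            else:
                loss_ord = nn.softmax_cross_entropy(logits, y_tr[sel] - 1)
            total = nn.scale(loss_ord, cfg.lambda_ord)
            rec_val = 0.0
            if use_rec:
                if cfg.rec_all_nodes:
                    rows_global = np.arange(batch.n_nodes)
                    group = len(gene_ids)
                    P = np.tile(node_features, (batch.n_graphs, 1))
                else:
                    rows_global = np.concatenate(
                        [sl.start + m for sl, m in zip(batch.node_slices, masks)]
                    )
                    group = len(masks[0])
                    P = np.concatenate([node_features[m] for m in masks])
                if group > 0:
                    Q = decode(enc, batch, model, rows=rows_global)
                    rec = nn.wasserstein_loss_grouped(
                        Q, P, group, eps=cfg.sinkhorn_eps, n_iter=cfg.sinkhorn_iters
                    )
                    rec_val = float(rec.data)
                    total = nn.add(total, nn.scale(rec, cfg.lambda_rec))
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"ordinal={float(loss_ord.data)}, rec={rec_val}"
                )
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            ord_sum += float(loss_ord.data)
            rec_sum += rec_val
            n_batches += 1

        record = {
            "epoch": epoch,
            "train_ord": ord_sum / max(n_batches, 1),
            "train_rec": rec_sum / max(n_batches, 1),
        }
        record["train_loss"] = combined_loss(
            record["train_ord"], record["train_rec"], cfg
        )
        if len(counts_va):
            va_logits, _ = _eval_on_batches(model, val_batches)
            if cfg.head == "ordinal":
                from .ordinal import ordinal_loss as _np_ord

                record["val_ord"] = _np_ord(va_logits, y_va)
            else:
                record["val_ord"] = float(
                    nn.softmax_cross_entropy(nn.Tensor(va_logits), y_va - 1).data
                )
            record["val_acc"] = float(
                (_predicted_states(va_logits, cfg) == y_va).mean()
            )
            metric = (
                -record["val_acc"]
                if cfg.early_stopping_metric == "accuracy"
                else record["val_ord"]
            )
            if metric < best_val - 1e-6:
                best_val = metric
                best_state = model.state_dict()
                patience_left = cfg.early_stopping_patience
                epochs_since_best = 0
            else:
                patience_left -= 1
                epochs_since_best += 1
                if cfg.lr_decay < 1.0 and epochs_since_best % cfg.lr_decay_patience == 0:
                    optimizer.lr *= cfg.lr_decay
            record["lr"] = optimizer.lr
        log.append(record)
        if len(counts_va) and patience_left <= 0:
            break

    if len(counts_va):
        model.load_state_dict(best_state)
    checkpoint["state"] = model.state_dict()
    return checkpoint, log


def rebuild_model(checkpoint: dict) -> tuple[ModelParams, TrainingConfig]:
    """Re-instantiate a model (weights + config) from a checkpoint dict."""
    cfg = TrainingConfig.from_dict(checkpoint["config"])
    node_dim = checkpoint["node_features"].shape[1]
    bank = cfg.rbf_bank()
    model = ModelParams(
        cfg.model_config(),
        node_dim,
        bank.n_kernels,
        len(checkpoint["states"]),
        np.random.default_rng(0),
    )
    model.load_state_dict(checkpoint["state"])
    return model, cfg


@dataclass
class PredictionResult:
    """Per-cell decoded states, cumulative probabilities and embeddings."""

    table: pd.DataFrame
    logits: np.ndarray
    embeddings: np.ndarray


def predict(
    x: ExpressionMatrix,
    checkpoint: dict,
    threshold: float | None = None,
) -> PredictionResult:
    """Annotate a query matrix with a trained checkpoint.

    Query genes are mapped by name onto the model's training gene list;
    missing genes are imputed as zero counts (with a warning). Less than 50%
    overlap aborts, since that indicates a reference/query mismatch.
    Deterministic: dropout is off and the count-noise seed is fixed.
    """
    model, cfg = rebuild_model(checkpoint)
    if threshold is not None:
        cfg.threshold = threshold
    gene_ids = list(checkpoint["gene_ids"])
    states = list(checkpoint["states"])
    col_of = {g: j for j, g in enumerate(x.gene_ids)}
    overlap = sum(g in col_of for g in gene_ids)
    if overlap < 0.5 * len(gene_ids):
        raise ValidationError(
            f"only {overlap}/{len(gene_ids)} model genes found in query; "
            "the query likely does not match the model's reference"
        )
    if overlap < len(gene_ids):
        warnings.warn(
            f"{len(gene_ids) - overlap} model genes missing from query; "
            "imputing zero counts"
        )
    counts = np.zeros((x.n_cells, len(gene_ids)), dtype=x.counts.dtype)
    for j, g in enumerate(gene_ids):
        if g in col_of:
            counts[:, j] = x.counts[:, col_of[g]]

    logits, embs = _forward_eval(
        model,
        counts,
        gene_ids,
        checkpoint["node_features"],
        cfg.rbf_bank(),
        cfg,
        noise_rng_key=_INFERENCE_NOISE_STREAM,
    )
    q = _predicted_states(logits, cfg)
    rows = {"cell_id": x.cell_ids, "predicted_state": [states[i - 1] for i in q], "q": q}
    if cfg.head == "ordinal":
        sigma, masses = cumulative_probabilities(logits)
        for j in range(sigma.shape[1]):
            rows[f"p_beyond_{states[j]}"] = sigma[:, j]
        for j, s in enumerate(states):
            rows[f"mass_{s}"] = masses[:, j]
    table = pd.DataFrame(rows)
    return PredictionResult(table=table, logits=logits, embeddings=embs)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Per-fold metrics plus confusion matrices and a mean +/- sd summary."""

    folds: pd.DataFrame
    confusions: list[np.ndarray] = field(default_factory=list)
    per_state: list[pd.DataFrame] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.folds["accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.folds["accuracy"].std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary(self) -> str:
        return f"{100 * self.mean_accuracy:.2f} ± {100 * self.sd_accuracy:.2f}%"


def cross_validate(
    x: ExpressionMatrix,
    labels: OrdinalStateSet,
    embeddings: NodeEmbeddingTable,
    cfg: TrainingConfig,
    folds: int = 5,
    repeats: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validation with repeats."""
    y = labels.labels_for(x.cell_ids)
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=cfg.seed % (2**31)
    )
    records, confusions, per_state = [], [], []
    state_idx = np.arange(1, labels.n_states + 1)
    for k, (tr, te) in enumerate(splitter.split(x.counts, y)):
        if len(np.unique(y[tr])) < labels.n_states:
            warnings.warn(f"fold {k}: training split is missing some states")
        ckpt, _ = train(x.subset_cells(tr), labels, embeddings, cfg)
        pred = predict(x.subset_cells(te), ckpt)
        q = pred.table["q"].to_numpy()
        acc = float((q == y[te]).mean())
        prec, rec, f1, support = precision_recall_fscore_support(
            y[te], q, labels=state_idx, zero_division=0
        )
        records.append(
            {"repeat": k // folds, "fold": k % folds, "accuracy": acc, "n_test": len(te)}
        )
        confusions.append(confusion_matrix(y[te], q, labels=state_idx))
        per_state.append(
            pd.DataFrame(
                {
                    "state": labels.states,
                    "precision": prec,
                    "recall": rec,
                    "f1": f1,
                    "support": support,
                }
            )
        )
    return CVResult(pd.DataFrame(records), confusions, per_state)


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    arrays = {f"param::{k}": v for k, v in checkpoint["state"].items()}
    arrays["node_features"] = checkpoint["node_features"]
    meta = {
        "config": checkpoint["config"],
        "gene_ids": checkpoint["gene_ids"],
        "states": checkpoint["states"],
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        state = {
            k.removeprefix("param::"): z[k] for k in z.files if k.startswith("param::")
        }
        return {
            "state": state,
            "config": meta["config"],
            "gene_ids": meta["gene_ids"],
            "states": meta["states"],
            "node_features": z["node_features"],
        }
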