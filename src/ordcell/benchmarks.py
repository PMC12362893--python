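"""Desk-scale benchmark protocols used by the acceptance suite.

All problem sizes here are deliberate reductions chosen to run on one CPU in
minutes while exercising the full pipeline: the strong-drift dataset keeps
the default 6-state / 1200-cell / 300-gene conditions with a small model
config (40 HVGs, hidden width 24); the ablation comparisons run on a smaller
moderately overlapping dataset. Sizes are fixed here, not tunable knobs.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .graphs import NodeEmbeddingTable
from .io_qc import ExpressionMatrix, OrdinalStateSet
from .simulate import SyntheticSpec, make_fixture_embeddings, simulate
from .train import CVResult, TrainingConfig, cross_validate, predict, train

#: drift (log-mean shift per state) regimes; "strong" is calibrated so that a
#: nearest-centroid baseline exceeds 0.95 held-out accuracy, "moderate"
#: leaves adjacent states heavily overlapping.
STRONG_DRIFT = 1.0
MODERATE_DRIFT = 0.35

#: cosine similarity of the informative-gene block in the fixture embeddings,
#: emulating the co-expression structure a compendium-trained table encodes.
EMBEDDING_BLOCK_CORR = 0.7


def small_model_config(seed: int, **overrides) -> TrainingConfig:
    """The benchmark model: 40 HVGs, hidden 24, 12 epochs of Adam."""
    base = dict(
        n_hvg=40,
        hidden_dim=24,
        batch_size=32,
        learning_rate=3e-3,
        max_epochs=10,
        early_stopping_patience=5,
        noise_sd=0.1,
        lambda_rec=0.1,
        seed=seed,
    )
    base.update(overrides)
    return TrainingConfig(**base)


def ordered_state_dataset(
    seed: int, drift: float = STRONG_DRIFT
) -> tuple[ExpressionMatrix, OrdinalStateSet, NodeEmbeddingTable]:
    """The default 6-state, 1200-cell, 300-gene dataset plus embeddings."""
    spec = SyntheticSpec(seed=seed, drift_per_state=drift)
    x, labels, truth = simulate(spec)
    emb = make_fixture_embeddings(
        x.gene_ids,
        dim=200,
        informative_block_corr=EMBEDDING_BLOCK_CORR,
        informative_genes=truth["informative_genes"],
        seed=seed,
    )
    return x, labels, emb


def cv_strong_drift(seed: int, folds: int = 5) -> CVResult:
    """Stratified k-fold cross-validation on the well-separated dataset."""
    x, labels, emb = ordered_state_dataset(seed, drift=STRONG_DRIFT)
    cfg = small_model_config(seed)
    return cross_validate(x, labels, emb, cfg, folds=folds, repeats=1)


def centroid_baseline_moderate_drift(seed: int) -> tuple[float, float]:
    """Nearest-centroid accuracy and adjacent-error fraction, all genes.

    A deliberately simple baseline showing that the moderate-drift conditions
    are learnable in principle and that errors there are intrinsically
    adjacent; used to contextualize the scaled-down model's behavior.
    """
    from sklearn.neighbors import NearestCentroid

    x, labels, _ = ordered_state_dataset(seed, drift=MODERATE_DRIFT)
    y = labels.labels_for(x.cell_ids)
    X = np.log1p(x.counts)
    tr, te = train_test_split(
        np.arange(x.n_cells), test_size=0.2, stratify=y, random_state=seed % (2**31)
    )
    q = NearestCentroid().fit(X[tr], y[tr]).predict(X[te])
    acc = float((q == y[te]).mean())
    errors = q != y[te]
    adj = float((np.abs(q - y[te])[errors] == 1).mean()) if errors.any() else 1.0
    return acc, adj


def adjacency_run(seed: int) -> tuple[float, float]:
    """Held-out accuracy and adjacent-error fraction under moderate overlap.

    Trains one 80/20 split on the moderate-drift dataset and returns
    (accuracy, fraction of misclassified cells predicted as a state adjacent
    to the truth).
    """
    x, labels, emb = ordered_state_dataset(seed, drift=MODERATE_DRIFT)
    y = labels.labels_for(x.cell_ids)
    tr, te = train_test_split(
        np.arange(x.n_cells), test_size=0.2, stratify=y, random_state=seed % (2**31)
    )
    cfg = small_model_config(seed)
    ckpt, _ = train(x.subset_cells(tr), labels, emb, cfg)
    q = predict(x.subset_cells(te), ckpt).table["q"].to_numpy()
    acc = float((q == y[te]).mean())
    errors = q != y[te]
    adj = float((np.abs(q - y[te])[errors] == 1).mean()) if errors.any() else 1.0
    return acc, adj


def _ablation_dataset(seed: int):
    spec = SyntheticSpec(
        n_states=4,
        cells_per_state=[150, 150, 150, 150],
        n_genes=200,
        n_informative_genes=50,
        drift_per_state=0.7,
        dispersion=0.3,
        seed=seed,
    )
    x, labels, truth = simulate(spec)
    return x, labels, truth


def ablation_accuracies(seed: int) -> dict[str, float]:
    """Held-out accuracy of the node-filler and classifier-head ablations.

    One train/test split per arm on a smaller overlapping dataset:
    distributed vs one-hot vs zero node features, and the ordinal head vs a
    plain softmax head (with distributed features).
    """
    x, labels, truth = _ablation_dataset(seed)
    y = labels.labels_for(x.cell_ids)
    tr, te = train_test_split(
        np.arange(x.n_cells), test_size=0.25, stratify=y, random_state=seed % (2**31)
    )
    xtr, xte = x.subset_cells(tr), x.subset_cells(te)
    distributed = make_fixture_embeddings(
        x.gene_ids,
        dim=200,
        informative_block_corr=EMBEDDING_BLOCK_CORR,
        informative_genes=truth["informative_genes"],
        seed=seed,
    )
    arms = {
        "distributed": (distributed, {}),
        "one_hot": (NodeEmbeddingTable("one_hot", 0), {}),
        "zeros": (NodeEmbeddingTable("zeros", 32), {}),
        "softmax_head": (distributed, {"head": "softmax"}),
    }
    out = {}
    for name, (emb, extra) in arms.items():
        cfg = small_model_config(
            seed,
            n_hvg=30,
            hidden_dim=16,
            max_epochs=8,
            early_stopping_patience=8,
            **extra,
        )
        ckpt, _ = train(xtr, labels, emb, cfg)
        q = predict(xte, ckpt).table["q"].to_numpy()
        out[name] = float((q == y[te]).mean())
    return out
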