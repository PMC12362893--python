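"""Synthetic scRNA-seq counts along an ordered series of cell states.

The generator emulates the structure the classifier is built for: a small set
of ordered states whose mean expression profiles drift gradually, so that
adjacent states overlap while distant ones separate. Counts are negative
binomial (gamma-Poisson) with per-cell library-size variation and
mean-dependent dropout (zero inflation), which reproduces the sparsity
pattern of real droplet data at the level needed to exercise the pipeline.

Informative genes have log-linear mean trajectories across the state order
with a random direction per gene; all remaining genes are state-independent.
Default state proportions follow the imbalance of a 6-timepoint epiblast
series, including one rare (~2%) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .graphs import NodeEmbeddingTable
from .io_qc import ExpressionMatrix, OrdinalStateSet

#: State frequencies of a 6-stage epiblast development series (E6.5..E7.75).
EPIBLAST_PROPORTIONS = (0.1701, 0.0640, 0.3789, 0.3106, 0.0691, 0.0173)


def _default_cells_per_state(n_states: int, total: int) -> list[int]:
    if n_states == len(EPIBLAST_PROPORTIONS):
        props = np.array(EPIBLAST_PROPORTIONS)
    else:
        props = np.full(n_states, 1.0 / n_states)
    counts = np.maximum(np.round(props * total).astype(int), 2)
    counts[-1] += total - counts.sum()  # make the total exact
    counts[-1] = max(counts[-1], 2)
    return [int(c) for c in counts]


@dataclass
class SyntheticSpec:
    """Parameters of the ordered-state count generator.

    drift_per_state is the shift in log mean expression between adjacent
    states for informative genes (natural-log scale); dispersion is the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2);
    dropout_logit_slope shifts the logit of the mean-dependent dropout
    probability (larger -> sparser).
    """

    n_states: int = 6
    cells_per_state: list[int] | None = None
    n_genes: int = 300
    n_informative_genes: int = 60
    drift_per_state: float = 1.0
    dispersion: float = 0.3
    library_size_range: tuple[float, float] = (0.6, 1.6)
    dropout_logit_slope: float = -1.0
    base_log_mean: float = np.log(2.0)
    base_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.cells_per_state is None:
            self.cells_per_state = _default_cells_per_state(self.n_states, 1200)
        if len(self.cells_per_state) != self.n_states:
            raise ValueError("cells_per_state length must equal n_states")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("more informative genes than genes")


def simulate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, OrdinalStateSet, dict]:
    """Draw a (cells x genes) count matrix with ordered-state structure.

    Returns the matrix, the per-cell labels with the ordered state list, and a
    ground-truth record (per-gene trajectory parameters, library factors).
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = int(sum(spec.cells_per_state))
    states = [f"state_{i + 1}" for i in range(spec.n_states)]
    y = np.concatenate(
        [np.full(c, s + 1) for s, c in enumerate(spec.cells_per_state)]
    )

    beta0 = rng.normal(spec.base_log_mean, spec.base_log_sd, spec.n_genes)
    informative = rng.choice(spec.n_genes, spec.n_informative_genes, replace=False)
    beta1 = np.zeros(spec.n_genes)
    beta1[informative] = rng.choice([-1.0, 1.0], spec.n_informative_genes)

    # state index s runs 0..n_states-1, centered so baseline is mid-trajectory
    s_centered = (y - 1) - (spec.n_states - 1) / 2.0
    log_mu = beta0[None, :] + spec.drift_per_state * s_centered[:, None] * beta1[None, :]
    mu = np.exp(log_mu)

    lib = rng.uniform(*spec.library_size_range, n_cells)
    mu_eff = mu * lib[:, None]

    if spec.dispersion > 1e-8:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mu_eff * spec.dispersion)
    else:
        lam = mu_eff
    counts = rng.poisson(lam).astype(np.int64)

    # mean-dependent zero inflation: low-expression genes drop out more
    p_drop = expit(spec.dropout_logit_slope - np.log(np.maximum(mu_eff, 1e-12)))
    counts[rng.random(counts.shape) < p_drop] = 0

    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    gene_ids = [f"gene_{j:04d}" for j in range(spec.n_genes)]
    x = ExpressionMatrix(counts, cell_ids, gene_ids)
    labels = OrdinalStateSet(states, dict(zip(cell_ids, (int(v) for v in y))))
    truth = {
        "beta0": beta0,
        "beta1": beta1,
        "informative_genes": [gene_ids[j] for j in sorted(informative)],
        "library_factors": lib,
        "state_of_cell": y,
        "mu": mu,
    }
    return x, labels, truth


def make_fixture_embeddings(
    gene_ids: list[str],
    dim: int = 200,
    informative_block_corr: float = 0.0,
    informative_genes: list[str] | None = None,
    seed: int = 0,
) -> NodeEmbeddingTable:
    """Random unit-norm gene vectors standing in for co-expression embeddings.

    This is a synthetic stand-in for distributed gene representations learned
    from co-expression compendia: vectors are isotropic random directions,
    optionally with the informative genes sharing a correlated block
    (pairwise cosine ~ informative_block_corr) so that prior-knowledge signal
    is testable.
    """
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    block = rng.normal(size=dim)
    block /= np.linalg.norm(block)
    info = set(informative_genes or [])
    rho = float(informative_block_corr)
    for g in gene_ids:
        v = rng.normal(size=dim)
        v /= np.linalg.norm(v)
        if g in info and rho > 0:
            v = np.sqrt(rho) * block + np.sqrt(1 - rho) * v
            v /= np.linalg.norm(v)
        vectors[g] = v
    return NodeEmbeddingTable(mode="distributed", dim=dim, vectors=vectors)
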