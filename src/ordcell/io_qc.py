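"""Reading expression matrices and labels, quality-control filters, HVG selection.

Counts are kept raw and unnormalized throughout: the downstream log-ratio
featurization is scale-free, so no library-size normalization is applied
anywhere in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input file parses but violates a domain constraint."""


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of raw nonnegative integer counts.

    Attributes
    ----------
    counts:
        Dense ``(n_cells, n_genes)`` array of nonnegative counts.
    cell_ids:
        Unique cell identifiers, one per row.
    gene_ids:
        Unique gene identifiers, one per column.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative entries found in count matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts[index],
            [self.cell_ids[i] for i in np.atleast_1d(index)],
            list(self.gene_ids),
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts[:, index],
            list(self.cell_ids),
            [self.gene_ids[i] for i in np.atleast_1d(index)],
        )


@dataclass
class OrdinalStateSet:
    """An ordered set of cell states plus per-cell labels.

    ``states`` is the biological sequence (e.g. embryonic timepoints
    E6.5 ... E7.75), never alphabetical. ``label_of_cell`` maps a cell id to a
    1-based index into that sequence.
    """

    states: list[str]
    label_of_cell: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValidationError("need at least 2 ordered states")
        if len(set(self.states)) != len(self.states):
            raise ValidationError("duplicate state names")
        for cell, idx in self.label_of_cell.items():
            if not 1 <= idx <= len(self.states):
                raise ValidationError(
                    f"cell {cell!r} labelled with out-of-range state index {idx}"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def labels_for(self, cell_ids: list[str]) -> np.ndarray:
        """1-based state indices for the given cells; raises if any unlabelled."""
        try:
            return np.array([self.label_of_cell[c] for c in cell_ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise ValidationError(f"cell {e.args[0]!r} has no label") from e


def _validate_counts(values: np.ndarray, where: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{where}: non-numeric entries")
    if np.any(~np.isfinite(arr.astype(float))):
        raise ValidationError(f"{where}: non-finite entries")
    if np.any(arr < 0):
        raise ValidationError(f"{where}: negative counts are not allowed")
    return arr


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a cells x genes count matrix.

    Formats:

    - ``csv``: dense, first column cell ids, header row gene ids.
    - ``mtx``: MatrixMarket coordinate file laid out genes x cells (the 10x
      cellranger triplet convention) with ``features.tsv`` / ``barcodes.tsv``
      sidecars in the same directory.
    - ``h5ad``: AnnData container; only ``X`` (raw counts expected),
      ``obs_names`` and ``var_names`` are used — layers/obsm are ignored.

    No normalization of any kind is applied.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(path.suffix, "")
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as e:
            raise ValidationError(f"failed to parse CSV {path}: {e}") from e
        counts = _validate_counts(df.to_numpy(), str(path))
        return ExpressionMatrix(counts, list(df.index), list(df.columns))
    if format == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as e:
            raise ValidationError(f"failed to parse MatrixMarket {path}: {e}") from e
        genes = _read_sidecar(path.parent / "features.tsv")
        cells = _read_sidecar(path.parent / "barcodes.tsv")
        dense = np.asarray(
            mat.todense() if sparse.issparse(mat) else mat
        )
        # cellranger layout: rows are genes, columns are cells
        counts = _validate_counts(dense.T, str(path))
        return ExpressionMatrix(counts, cells, genes)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        dense = np.asarray(x.todense() if sparse.issparse(x) else x)
        counts = _validate_counts(dense, str(path))
        return ExpressionMatrix(
            counts, list(adata.obs_names), list(adata.var_names)
        )
    raise ValueError(f"unknown expression format {format!r} for {path}")


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise ValidationError(f"missing MatrixMarket sidecar file {path}")
    names = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    return names


def write_expression(x: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a matrix back out; inverse of :func:`read_expression` for csv/mtx."""
    path = Path(path)
    if format == "csv":
        pd.DataFrame(x.counts, index=x.cell_ids, columns=x.gene_ids).to_csv(path)
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(x.counts.T))
        (path.parent / "features.tsv").write_text("\n".join(x.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(x.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path, states: list[str]) -> OrdinalStateSet:
    """Read a two-column TSV (cell_id, state_name) against an ordered state list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "state"], dtype=str)
    index_of = {s: i + 1 for i, s in enumerate(states)}
    mapping: dict[str, int] = {}
    for cell, state in zip(df["cell_id"], df["state"]):
        if state not in index_of:
            raise ValidationError(f"label file {path}: unknown state {state!r}")
        mapping[cell] = index_of[state]
    return OrdinalStateSet(list(states), mapping)


def write_labels(labels: OrdinalStateSet, path: str | Path) -> None:
    lines = [
        f"{cell}\t{labels.states[idx - 1]}" for cell, idx in labels.label_of_cell.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def qc_filter(
    x: ExpressionMatrix,
    min_genes_per_cell: int = 100,
    min_cells_per_gene: int = 10,
) -> ExpressionMatrix:
    """Remove low-coverage cells, then rarely expressed genes.

    Cells expressing (count > 0) fewer than ``min_genes_per_cell`` genes are
    dropped first; genes expressed in fewer than ``min_cells_per_gene`` of the
    *remaining* cells are dropped second.
    """
    nonzero = x.counts > 0
    keep_cells = np.flatnonzero(nonzero.sum(axis=1) >= min_genes_per_cell)
    if keep_cells.size == 0:
        raise ValidationError("qc_filter removed every cell")
    out = x.subset_cells(keep_cells)
    keep_genes = np.flatnonzero((out.counts > 0).sum(axis=0) >= min_cells_per_gene)
    if keep_genes.size == 0:
        raise ValidationError("qc_filter removed every gene")
    return out.subset_genes(keep_genes)


def gene_dispersion(counts: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (variance / mean) of log1p-transformed counts.

    Genes with zero mean get dispersion 0.
    """
    logged = np.log1p(counts.astype(float))
    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def select_hvgs(
    x: ExpressionMatrix,
    n_hvg: int = 600,
    statistic=gene_dispersion,
) -> ExpressionMatrix:
    """Keep the ``n_hvg`` most variable genes.

    Ranking uses ``statistic`` (default: dispersion of log1p counts). Ties at
    the cutoff are broken lexicographically by gene id (smaller id wins).
    The original gene order is preserved among the kept genes.
    """
    if x.n_genes <= n_hvg:
        warnings.warn(
            f"requested {n_hvg} HVGs but matrix has only {x.n_genes} genes; keeping all"
        )
        return x
    disp = np.asarray(statistic(x.counts), dtype=float)
    order = sorted(range(x.n_genes), key=lambda j: (-disp[j], x.gene_ids[j]))
    keep = np.array(sorted(order[:n_hvg]))
    return x.subset_genes(keep)
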