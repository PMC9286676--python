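"""Count-matrix containers, standard-format I/O, QC filtering and log-normalization.

The pipeline operates on a sparse genes x cells raw count matrix with string
identifiers on both axes, a per-cell annotation table (group label such as
cell-type subclass, plus sex/region/subcluster), and the log-normalized
matrix derived from it.  Counts are exchanged on disk as Matrix Market
coordinate files with ``features.tsv`` / ``barcodes.tsv`` sidecars, the
layout 10x-style exports use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QCReport",
    "FormatError",
    "read_counts",
    "read_annotation",
    "write_counts",
    "subset_cells",
    "qc_filter",
    "log_normalize",
    "rank_variable_genes",
]

#: Cell-type subclass display order used by the hippocampal analyses
#: (non-neuronal types, GABAergic neurons, then the glutamatergic
#: tri-synaptic populations).
CANONICAL_GROUPS = (
    "Astro", "Oligo", "Endo", "Micro-PVM",
    "Lamp5", "Vip", "Pvalb", "Sncg", "Sst",
    "DG", "CA1-ProS", "CA2", "CA3",
)


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        counts = pd.Series(ids).value_counts()
        dup = counts[counts > 1].index[0]
        raise FormatError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes as rows, cells as columns."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in matrix")
        return int(idx[0])

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and (self.values != other.values).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same axes as its source counts.

    An entry is zero iff the raw count was zero: normalization rescales a
    cell's counts to ``scale_factor`` total and applies log1p, which maps
    0 to 0 and keeps the sparsity pattern.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in matrix")
        return int(idx[0])

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense vector of a single gene's normalized values across cells."""
        return np.asarray(self.values[self.gene_index(gene)].todense()).ravel()


@dataclass
class QCReport:
    """Counts removed by each axis of the QC filter."""

    cells_removed: int
    genes_removed: int
    min_cells: int
    min_features: int


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_column(path: str | Path, what: str) -> np.ndarray:
    try:
        tab = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return np.array([], dtype=object)
    return tab.iloc[:, 0].to_numpy(dtype=object)


def read_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a Matrix Market counts file with feature/barcode sidecars.

    The ``.mtx`` file stores 1-based (gene, cell, count) triplets; features
    and barcodes are header-less TSVs whose row order defines the axes.
    Raises :class:`FormatError` when header dimensions disagree with the
    sidecar row counts, on duplicate identifiers, or on negative counts.
    """
    raw = scipy.io.mmread(str(mtx_path))
    values = sp.csr_matrix(raw)
    gene_ids = _read_id_column(features_path, "gene")
    cell_ids = _read_id_column(barcodes_path, "cell")
    if values.shape[0] != len(gene_ids):
        raise FormatError(
            f"{mtx_path}: header declares {values.shape[0]} genes but "
            f"{features_path} has {len(gene_ids)} rows"
        )
    if values.shape[1] != len(cell_ids):
        raise FormatError(
            f"{mtx_path}: header declares {values.shape[1]} cells but "
            f"{barcodes_path} has {len(cell_ids)} rows"
        )
    if values.nnz and values.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative count entry")
    values.data = values.data.astype(np.int64)
    return CountMatrix(values, gene_ids, cell_ids)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-cell annotation TSV (cell_id, group, sex, region, subcluster)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in ann.columns or "group" not in ann.columns:
        raise FormatError(f"{path}: annotation needs 'cell_id' and 'group' columns")
    if ann["cell_id"].duplicated().any():
        dup = ann.loc[ann["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"{path}: duplicate cell_id {dup!r}")
    return ann


def write_counts(
    matrix: CountMatrix,
    annotation: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv (+ annotation.tsv).

    Counts are written as an integer-field coordinate file so a read
    round-trip is exact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    coo = matrix.values.tocoo()
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    feat = pd.DataFrame({"gene_id": matrix.gene_ids, "gene_symbol": matrix.gene_ids})
    feat.to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    if annotation is not None:
        paths["annotation"] = out / "annotation.tsv"
        annotation.to_csv(paths["annotation"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# subsetting, QC, normalization


def subset_cells(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    keep_groups: set[str] | list[str],
    group_key: str = "group",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Keep only cells whose group label is in ``keep_groups``.

    The gene axis is untouched; the annotation is filtered in lockstep and
    re-ordered to match the matrix columns.
    """
    keep_groups = set(keep_groups)
    if not keep_groups:
        raise ValueError("keep_groups must be nonempty")
    ann = annotation.set_index("cell_id").loc[matrix.cell_ids].reset_index()
    mask = ann[group_key].isin(keep_groups).to_numpy()
    if not mask.any():
        observed = sorted(ann[group_key].unique())
        raise ValueError(
            f"no cells match keep_groups={sorted(keep_groups)}; observed groups {observed}"
        )
    sub = CountMatrix(
        matrix.values[:, mask].tocsr(), matrix.gene_ids, matrix.cell_ids[mask]
    )
    return sub, ann.loc[mask].reset_index(drop=True)


def qc_filter(
    matrix: CountMatrix,
    min_cells: int = 1,
    min_features: int = 100,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-complexity cells, then rarely detected genes.

    Cells with fewer than ``min_features`` detected genes (raw count > 0)
    are dropped first; genes then detected in fewer than ``min_cells``
    remaining cells are dropped.  These are the matrix-creation semantics
    of the standard single-cell toolkit, and the order makes the operation
    idempotent at the default ``min_cells=1``.
    """
    if min_cells < 0 or min_features < 0:
        raise ValueError("thresholds must be non-negative")
    detected = matrix.values.copy()
    detected.data = np.ones_like(detected.data)
    feats_per_cell = np.asarray(detected.sum(axis=0)).ravel()
    cell_mask = feats_per_cell >= min_features
    if not cell_mask.any():
        raise ValueError(
            f"qc_filter removed all cells (min_features={min_features})"
        )
    kept = detected[:, cell_mask]
    cells_per_gene = np.asarray(kept.sum(axis=1)).ravel()
    gene_mask = cells_per_gene >= min_cells
    report = QCReport(
        cells_removed=int((~cell_mask).sum()),
        genes_removed=int((~gene_mask).sum()),
        min_cells=min_cells,
        min_features=min_features,
    )
    logger.info(
        "qc_filter: removed %d cells (<%d features) and %d genes (<%d cells)",
        report.cells_removed, min_features, report.genes_removed, min_cells,
    )
    out = CountMatrix(
        matrix.values[gene_mask][:, cell_mask].tocsr(),
        matrix.gene_ids[gene_mask],
        matrix.cell_ids[cell_mask],
    )
    return out, report


def log_normalize(matrix: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """LogNormalize: value(g, c) = ln(1 + count(g, c) * scale_factor / total(c)).

    Every cell's counts are rescaled to a common ``scale_factor`` total and
    log1p-transformed, so normalized values are comparable across cells with
    different library sizes.  Cells with zero total count must be removed
    beforehand (``qc_filter``).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(matrix.values.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = matrix.cell_ids[totals == 0][0]
        raise ValueError(
            f"cell {bad!r} has zero total count; run qc_filter before log_normalize"
        )
    csc = matrix.values.tocsc().astype(float)
    # scale each column by scale_factor / total, then log1p on stored entries
    scale = scale_factor / totals
    norm = csc.multiply(sp.csr_matrix(scale)).tocsr()
    norm.data = np.log1p(norm.data)
    return NormalizedMatrix(norm, matrix.gene_ids, matrix.cell_ids, scale_factor)


def rank_variable_genes(matrix: CountMatrix, n_top: int = 2000) -> np.ndarray:
    """Rank genes by variance-stabilized variance and return the top symbols.

    A mean-variance trend is fitted on log10 scale with a quadratic
    polynomial over expressed genes; counts are standardized with the
    fitted (trend) standard deviation, clipped at sqrt(n_cells), and genes
    are ranked by the variance of the standardized counts.  This is an
    optional gene-selection pass-through: no downstream stage here depends
    on it, because profiling and coupling operate on named gene sets.
    """
    X = matrix.values.astype(float)
    n_cells = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = var * n_cells / max(n_cells - 1, 1)
    expressed = (mean > 0) & (var > 0)
    coef = np.polyfit(np.log10(mean[expressed]), np.log10(var[expressed]), deg=2)
    trend_sd = np.zeros_like(mean)
    trend_sd[expressed] = np.sqrt(10 ** np.polyval(coef, np.log10(mean[expressed])))
    clip = np.sqrt(n_cells)
    scores = np.zeros(len(mean))
    dense = np.asarray(X.todense())
    for i in np.flatnonzero(expressed):
        z = np.clip((dense[i] - mean[i]) / trend_sd[i], -clip, clip)
        scores[i] = z.var(ddof=1)
    order = np.argsort(-scores, kind="stable")
    return matrix.gene_ids[order[:n_top]]
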