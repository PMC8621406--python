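"""QC filtering and pseudobulk aggregation of labeled single-cell counts.

The analysis starts from a cell x gene UMI count matrix whose cells carry
one of the four germline cell-type labels.  Quality control keeps genes
detected in at least 3 cells and cells with at least 200 detected genes.
The retained matrix is collapsed per gene into a :class:`StageProfile`: the
mean log2(CPM + 1) and the percentage of expressing cells within each cell
type.  Everything downstream (stage classification, enrichment, shift
scoring) consumes this 4 + 4 column profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CELL_TYPES

log = logging.getLogger(__name__)

MIN_CELLS_PER_GENE = 3
MIN_GENES_PER_CELL = 200


@dataclass
class LabeledCounts:
    """A cell x gene count matrix with per-cell germline cell-type labels."""

    counts: sp.csr_matrix  # cells x genes, non-negative integers
    cell_types: np.ndarray  # str per cell
    gene_ids: np.ndarray  # unique str per gene
    cell_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.array(
                [f"cell{i}" for i in range(self.counts.shape[0])], dtype=object
            )
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_types) != n_cells:
            raise ValueError(
                f"{len(self.cell_types)} cell labels for {n_cells} cells"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} genes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        unknown = set(self.cell_types) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class StageProfile:
    """Per-gene pseudobulk expression profile over the four cell types.

    Attributes
    ----------
    mean_expr
        genes x 4 frame of mean log2(CPM + 1) per cell type.
    pct_expr
        genes x 4 frame of the percentage (0-100) of that cell type's
        cells with a nonzero count for the gene.
    """

    mean_expr: pd.DataFrame
    pct_expr: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.mean_expr, self.pct_expr):
            if list(df.columns) != list(CELL_TYPES):
                raise ValueError(f"profile columns must be {CELL_TYPES}")
        if not self.mean_expr.index.equals(self.pct_expr.index):
            raise ValueError("mean_expr and pct_expr must share a gene index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.mean_expr.index

    def expressed_mask(self, mode: str = "mean") -> pd.Series:
        """Boolean per gene: any nonzero value across cell types."""
        df = self.mean_expr if mode == "mean" else self.pct_expr
        return (df > 0).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        mean = self.mean_expr.add_prefix("mean_")
        pct = self.pct_expr.add_prefix("pct_")
        out = pd.concat([mean, pct], axis=1)
        out.index.name = "gene_id"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StageProfile":
        mean = df[[f"mean_{ct}" for ct in CELL_TYPES]].copy()
        mean.columns = list(CELL_TYPES)
        pct = df[[f"pct_{ct}" for ct in CELL_TYPES]].copy()
        pct.columns = list(CELL_TYPES)
        return cls(mean_expr=mean, pct_expr=pct)


def qc_filter(
    data: LabeledCounts,
    min_cells: int = MIN_CELLS_PER_GENE,
    min_genes: int = MIN_GENES_PER_CELL,
    iterative: bool = False,
) -> LabeledCounts:
    """Keep genes detected in >= min_cells cells and cells with >= min_genes genes.

    Both masks are computed on the input matrix and applied jointly in one
    pass; with ``iterative=True`` the two filters are re-applied until a
    fixed point (each pass recomputes both masks on the surviving matrix).
    An empty result triggers a warning, not an error.
    """
    if data.n_cells == 0 or data.n_genes == 0:
        raise ValueError("qc_filter requires a non-empty matrix")

    counts = data.counts
    cell_types = data.cell_types
    gene_ids = data.gene_ids
    cell_ids = data.cell_ids
    while True:
        detected = counts > 0
        gene_mask = np.asarray(detected.sum(axis=0)).ravel() >= min_cells
        cell_mask = np.asarray(detected.sum(axis=1)).ravel() >= min_genes
        if gene_mask.all() and cell_mask.all():
            break
        counts = counts[cell_mask][:, gene_mask]
        cell_types = cell_types[cell_mask]
        cell_ids = cell_ids[cell_mask]
        gene_ids = gene_ids[gene_mask]
        if not iterative:
            break
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            break

    if counts.shape[0] == 0 or counts.shape[1] == 0:
        warnings.warn("QC filtering removed all cells or all genes", stacklevel=2)
    log.info(
        "QC: kept %d/%d genes and %d/%d cells",
        counts.shape[1], data.n_genes, counts.shape[0], data.n_cells,
    )
    return LabeledCounts(
        counts=counts, cell_types=cell_types, gene_ids=gene_ids, cell_ids=cell_ids
    )


def aggregate(data: LabeledCounts) -> StageProfile:
    """Collapse counts into per-gene mean log2(CPM + 1) and percent-expressing.

    CPM is computed per cell over the current (post-QC) gene set:
    ``count * 1e6 / cell_total``.  For each gene and cell type, mean_expr is
    the mean of log2(CPM + 1) over that type's cells and pct_expr the
    percentage of those cells with a nonzero count.  All four germline cell
    types must be present.
    """
    present = set(data.cell_types)
    missing = [ct for ct in CELL_TYPES if ct not in present]
    if missing:
        raise ValueError(f"germline cell type(s) absent from input: {missing}")

    counts = sp.csr_matrix(data.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    # cells with zero total contribute log2(0+1)=0 everywhere
    scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=totals > 0)
    cpm = sp.diags(scale) @ counts
    logcpm = cpm.copy()
    logcpm.data = np.log2(logcpm.data + 1.0)

    mean_rows = {}
    pct_rows = {}
    for ct in CELL_TYPES:
        mask = data.cell_types == ct
        n = int(mask.sum())
        sub_log = logcpm[mask]
        sub_det = data.counts[mask] > 0
        mean_rows[ct] = np.asarray(sub_log.sum(axis=0)).ravel() / n
        pct_rows[ct] = 100.0 * np.asarray(sub_det.sum(axis=0)).ravel() / n

    idx = pd.Index(data.gene_ids, name="gene_id")
    mean_expr = pd.DataFrame(mean_rows, index=idx, columns=list(CELL_TYPES))
    pct_expr = pd.DataFrame(pct_rows, index=idx, columns=list(CELL_TYPES))
    return StageProfile(mean_expr=mean_expr, pct_expr=pct_expr)


def concat_counts(datasets: list[LabeledCounts]) -> LabeledCounts:
    """Concatenate matrices sharing a gene set (no batch correction applied)."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    ref = list(datasets[0].gene_ids)
    for d in datasets[1:]:
        if list(d.gene_ids) != ref:
            raise ValueError("datasets must share an identical gene_id ordering")
    if len(datasets) > 1:
        log.warning(
            "concatenating %d matrices without batch correction", len(datasets)
        )
    return LabeledCounts(
        counts=sp.vstack([d.counts for d in datasets], format="csr"),
        cell_types=np.concatenate([d.cell_types for d in datasets]),
        gene_ids=np.asarray(ref, dtype=object),
        cell_ids=np.concatenate([d.cell_ids for d in datasets]),
    )
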