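"""Reading and writing the pipeline's tabular and matrix formats.

Count matrices travel as MatrixMarket (cells x genes) with sidecar gene
and cell TSVs, or as a single dense TSV (cells in rows); every other table
is TSV with a header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import StageCategory, category_from_string
from .ingest import LabeledCounts, StageProfile


def write_counts_mtx(data: LabeledCounts, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + genes.tsv + cells.tsv (with labels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(data.counts))
    pd.Series(data.gene_ids).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=["gene_id"]
    )
    pd.DataFrame({"cell_id": data.cell_ids, "cell_type": data.cell_types}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_counts_mtx(indir: str | Path) -> LabeledCounts:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"]
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return LabeledCounts(
        counts=counts,
        cell_types=cells["cell_type"].to_numpy(dtype=object),
        gene_ids=genes.to_numpy(dtype=object),
        cell_ids=cells["cell_id"].to_numpy(dtype=object),
    )


def read_counts_dense(
    counts_path: str | Path, labels_path: str | Path
) -> LabeledCounts:
    """Dense TSV (rows = cells, columns = genes) plus a cell-label TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels = labels.reindex(df.index)
    if labels.iloc[:, 0].isna().any():
        missing = labels.index[labels.iloc[:, 0].isna()][:5]
        raise ValueError(f"cells without a label, e.g. {list(missing)}")
    return LabeledCounts(
        counts=sp.csr_matrix(df.to_numpy()),
        cell_types=labels.iloc[:, 0].to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
        cell_ids=df.index.to_numpy(dtype=object),
    )


def write_profile(profile: StageProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def read_profile(path: str | Path) -> StageProfile:
    return StageProfile.from_frame(pd.read_csv(path, sep="\t", index_col="gene_id"))


def write_categories(categories: pd.DataFrame, path: str | Path) -> None:
    out = categories.copy()
    out["category"] = [c.value for c in out["category"]]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_categories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["category"] = df["category"].map(category_from_string)
    df["rank"] = df["rank"].astype("Int64")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"gene_id", "chromosome"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return df


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"child_id", "parent_id", "branch", "mechanism"}
    if not required <= set(df.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    return df


def read_chrom_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index("chrom")["bp"]


def categories_series(categories: pd.DataFrame) -> pd.Series:
    """The gene -> StageCategory series used by enrichment and pair scoring."""
    return categories["category"]
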