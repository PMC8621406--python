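"""Chromosomal composition of stage categories and Fisher enrichment.

The X and dot (4th) chromosomes of *D. melanogaster* carry an excess of
mitotic (spermatogonia-expressed) genes and a deficit of meiotic genes —
the signature of meiotic sex chromosome inactivation.  This module builds
the chromosome x category contingency counts, tests each non-autosomal
chromosome against the major autosomes (2L, 2R, 3L, 3R) with two-sided
Fisher exact tests, and computes the normalized per-stage ratios
(proportion on the focal chromosome over proportion on the autosomes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import ALL_CATEGORIES, AUTOSOMES, CHROMOSOMES, StageCategory

log = logging.getLogger(__name__)

#: Pooling of sparse categories for testing.  The default pools the few
#: postmeiotic genes with the meiotic ones and keeps meiosis_postmeiosis
#: separate; "all_meiotic" additionally pools meiosis_postmeiosis.
POOLINGS: dict[str, dict[StageCategory, str]] = {
    "none": {c: c.value for c in ALL_CATEGORIES},
    "meiosis_postmeiosis": {
        StageCategory.MITOSIS: "mitosis",
        StageCategory.MITOSIS_MEIOSIS: "mitosis_meiosis",
        StageCategory.MEIOSIS: "meiosis+postmeiosis",
        StageCategory.POSTMEIOSIS: "meiosis+postmeiosis",
        StageCategory.MEIOSIS_POSTMEIOSIS: "meiosis_postmeiosis",
        StageCategory.NOT_EXPRESSED: "not_expressed",
    },
    "all_meiotic": {
        StageCategory.MITOSIS: "mitosis",
        StageCategory.MITOSIS_MEIOSIS: "mitosis_meiosis",
        StageCategory.MEIOSIS: "meiotic+",
        StageCategory.POSTMEIOSIS: "meiotic+",
        StageCategory.MEIOSIS_POSTMEIOSIS: "meiotic+",
        StageCategory.NOT_EXPRESSED: "not_expressed",
    },
}


@dataclass
class EnrichmentResult:
    """One category-vs-rest Fisher comparison of a stratum against autosomes."""

    stratum: str
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    direction: str | None  # "enriched", "depleted" or None when undefined

    def to_dict(self) -> dict:
        ((a, b), (c, d)) = self.table
        return {
            "stratum": self.stratum,
            "category": self.category,
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "direction": self.direction,
        }


def count_by_chrom(
    categories: pd.Series, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Dense chromosome x category gene-count table.

    ``categories`` maps gene_id -> StageCategory; ``annotations`` must carry
    gene_id (index or column) and chromosome.  Genes without an annotation
    are excluded with a warning; unknown chromosomes are rejected.
    """
    annot = annotations
    if "gene_id" in annot.columns:
        annot = annot.set_index("gene_id")
    unknown = set(annot["chromosome"].unique()) - set(CHROMOSOMES)
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")

    missing = categories.index.difference(annot.index)
    if len(missing) > 0:
        warnings.warn(
            f"{len(missing)} categorized genes lack an annotation and are "
            f"excluded (first few: {list(missing[:5])})",
            stacklevel=2,
        )
    common = categories.index.intersection(annot.index)
    table = pd.DataFrame(
        0, index=list(CHROMOSOMES), columns=[c.value for c in ALL_CATEGORIES]
    )
    grouped = (
        pd.DataFrame(
            {
                "chromosome": annot.loc[common, "chromosome"],
                "category": [c.value for c in categories[common]],
            }
        )
        .groupby(["chromosome", "category"], observed=True)
        .size()
    )
    for (chrom, cat), n in grouped.items():
        table.loc[chrom, cat] = int(n)
    table.index.name = "chromosome"
    return table


def _pool(counts: pd.DataFrame, pooling: str) -> pd.DataFrame:
    mapping = POOLINGS[pooling]
    pooled = counts.T.groupby(
        counts.columns.map(lambda name: mapping[StageCategory(name)])
    ).sum().T
    return pooled


def fisher_vs_autosomes(
    counts: pd.DataFrame,
    chrom: str,
    category: str,
    pooling: str = "meiosis_postmeiosis",
    include_not_expressed: bool = False,
) -> EnrichmentResult:
    """Two-sided Fisher exact: category composition of chrom vs autosomes.

    The 2x2 table is [[n_cat_C, n_other_C], [n_cat_A, n_other_A]] where A is
    the pooled major autosomes.  NOT_EXPRESSED genes are excluded from the
    denominators unless ``include_not_expressed`` (used for the
    expressed-vs-not comparison, e.g. on the Y chromosome).
    """
    pooled = _pool(counts, pooling)
    if category not in pooled.columns:
        raise ValueError(
            f"category {category!r} not present under pooling {pooling!r}"
        )
    cols = list(pooled.columns)
    if not include_not_expressed and category != "not_expressed":
        cols = [c for c in cols if c != "not_expressed"]
    focal = pooled.loc[chrom, cols]
    auto = pooled.loc[list(AUTOSOMES), cols].sum(axis=0)

    a = int(focal[category])
    b = int(focal.sum() - focal[category])
    c = int(auto[category])
    d = int(auto.sum() - auto[category])
    table = ((a, b), (c, d))

    if min(a + b, c + d, a + c, b + d) == 0:
        log.warning("zero margin in %s/%s table %s", chrom, category, table)
        return EnrichmentResult(chrom, category, table, np.nan, 1.0, None)

    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    direction = "enriched" if odds > 1 else ("depleted" if odds < 1 else None)
    return EnrichmentResult(chrom, category, table, float(odds), float(p), direction)


def enrich_all(
    counts: pd.DataFrame,
    strata: tuple[str, ...] = ("4", "X", "Y"),
    pooling: str = "meiosis_postmeiosis",
) -> pd.DataFrame:
    """All stratum x category Fisher tests with BH-adjusted q per stratum.

    Raw p values drive the significance flags (as in the single-test
    convention for these comparisons); Benjamini-Hochberg q values are
    reported alongside, adjusted within each stratum's family of category
    tests.
    """
    rows = []
    pooled_cols = [
        c for c in _pool(counts, pooling).columns if c != "not_expressed"
    ]
    for chrom in strata:
        results = [
            fisher_vs_autosomes(counts, chrom, cat, pooling=pooling)
            for cat in pooled_cols
        ]
        q = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            row = r.to_dict()
            row["q"] = float(qv)
            rows.append(row)
    return pd.DataFrame(rows)


def normalized_ratio(
    counts: pd.DataFrame,
    chrom: str,
    category: str,
    pooling: str = "none",
) -> float:
    """Category proportion on a chromosome over its proportion on autosomes.

    ``(n_cat_C / n_C) / (n_cat_A / n_A)`` with n_* the total gene counts.
    Returns NaN when the focal chromosome has no genes or the autosomes
    have no genes of the category.
    """
    pooled = _pool(counts, pooling)
    n_c = pooled.loc[chrom].sum()
    n_cat_c = pooled.loc[chrom, category]
    auto = pooled.loc[list(AUTOSOMES)].sum(axis=0)
    n_a = auto.sum()
    n_cat_a = auto[category]
    if n_c == 0 or n_cat_a == 0 or n_a == 0:
        log.warning("normalized_ratio undefined for %s/%s", chrom, category)
        return float("nan")
    return float((n_cat_c / n_c) / (n_cat_a / n_a))


def ratio_table(
    counts: pd.DataFrame,
    strata: tuple[str, ...] = ("4", "X", "Y"),
    pooling: str = "none",
) -> pd.DataFrame:
    """Normalized ratios for every stratum and expressed category."""
    cats = [
        c for c in _pool(counts, pooling).columns if c != "not_expressed"
    ]
    return pd.DataFrame(
        {
            chrom: {
                cat: normalized_ratio(counts, chrom, cat, pooling=pooling)
                for cat in cats
            }
            for chrom in strata
        }
    ).T.rename_axis("chromosome")
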