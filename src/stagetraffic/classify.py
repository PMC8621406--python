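"""Stage-category assignment by row-scaled hierarchical clustering.

Each germline-expressed gene is represented by its 4-vector of mean
log2(CPM + 1) over the germline cell types (or, in the robustness variant,
its percent-expressing 4-vector).  Rows are z-scored, clustered by
complete-linkage agglomerative clustering on Euclidean distance, the tree
is cut into k clusters (default 7), and each cluster is mapped to one of
the five stage categories from the cell types its centroid is enriched in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import CELL_TYPES, StageCategory
from .ingest import StageProfile

log = logging.getLogger(__name__)

# Contiguous enriched sets and the category each maps to.  Singleton
# spermatocyte sets ({early} or {late}) still denote meiosis.
_CONTIGUOUS_SETS: tuple[tuple[frozenset[str], StageCategory], ...] = (
    (frozenset({"spermatogonia"}), StageCategory.MITOSIS),
    (frozenset({"spermatogonia", "early_spermatocytes"}), StageCategory.MITOSIS_MEIOSIS),
    (frozenset({"early_spermatocytes"}), StageCategory.MEIOSIS),
    (frozenset({"late_spermatocytes"}), StageCategory.MEIOSIS),
    (frozenset({"early_spermatocytes", "late_spermatocytes"}), StageCategory.MEIOSIS),
    (frozenset({"late_spermatocytes", "spermatids"}), StageCategory.MEIOSIS_POSTMEIOSIS),
    (frozenset({"spermatids"}), StageCategory.POSTMEIOSIS),
)


@dataclass
class ClusterAssignment:
    """Result of cutting the dendrogram into k clusters."""

    labels: pd.Series  # gene_id -> cluster id in 1..k
    centroids: pd.DataFrame  # cluster id x 4, mean scaled expression
    categories: dict[int, StageCategory] | None = None  # filled by assign_categories

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def scale_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sample SD 1 (ddof=1).

    Constant rows (SD = 0), including all-zero rows, map to all-zeros.
    """
    arr = np.asarray(values, dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (arr - mean) / sd
    scaled[np.broadcast_to(sd == 0, scaled.shape)] = 0.0
    return pd.DataFrame(scaled, index=values.index, columns=values.columns)


def cluster_stages(scaled: pd.DataFrame, k: int = 7) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering of scaled rows, cut at k.

    Euclidean distance between the scaled 4-vectors; genes are processed in
    canonically sorted gene_id order so the result is independent of input
    row order.
    """
    n = scaled.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} genes")

    ordered = scaled.sort_index(kind="stable")
    if n == 1:
        flat = np.ones(1, dtype=int)
    else:
        z = linkage(ordered.to_numpy(), method="complete", metric="euclidean")
        flat = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance for determinism
    relabel: dict[int, int] = {}
    for c in flat:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    labels = pd.Series(
        [relabel[c] for c in flat], index=ordered.index, name="cluster_id"
    )
    centroids = ordered.groupby(labels).mean()
    centroids.index.name = "cluster_id"
    return ClusterAssignment(labels=labels, centroids=centroids)


def _nearest_contiguous(centroid: pd.Series) -> StageCategory:
    """Fallback mapping for non-contiguous or 3+-type enriched sets.

    Picks the contiguous candidate set with the largest mean centroid value
    over its members (centroid mass), ties broken in stage order.
    """
    best: StageCategory | None = None
    best_mass = -np.inf
    for cells, cat in _CONTIGUOUS_SETS:
        mass = centroid[list(cells)].mean()
        if mass > best_mass + 1e-12:
            best_mass = mass
            best = cat
    assert best is not None
    return best


def assign_categories(
    assignment: ClusterAssignment,
    theta: float = 0.0,
    rel_enrich: float = 0.5,
) -> pd.Series:
    """Map each cluster, then each gene, to a stage category.

    A cluster's "enriched set" is the cell types whose centroid value
    exceeds both ``theta`` and ``rel_enrich`` times the centroid's peak:
    the relative criterion keeps cell types sitting marginally above the
    scaled mean (z just over 0) from being called enriched alongside a
    dominant peak, which would be unstable to sampling noise.  The set is
    mapped: {SPG} -> mitosis; {SPG, early} -> mitosis_meiosis; any
    spermatocyte-only set -> meiosis; {late, SPT} -> meiosis_postmeiosis;
    {SPT} -> postmeiosis.  Non-contiguous or 3+-type sets fall back to the
    nearest contiguous set by centroid mass; an empty set falls back to the
    argmax cell type.  Both fallbacks are logged.
    """
    cat_by_cluster: dict[int, StageCategory] = {}
    lookup = dict(_CONTIGUOUS_SETS)
    for cluster_id, centroid in assignment.centroids.iterrows():
        cutoff = theta
        if centroid.max() > 0:
            cutoff = max(theta, rel_enrich * centroid.max())
        enriched = frozenset(ct for ct in CELL_TYPES if centroid[ct] > cutoff)
        if not enriched:
            top = centroid.idxmax()
            cat = lookup[frozenset({top})]
            log.info(
                "cluster %s: empty enriched set, assigned by argmax (%s)",
                cluster_id, top,
            )
        elif enriched in lookup:
            cat = lookup[enriched]
        else:
            cat = _nearest_contiguous(centroid)
            log.info(
                "cluster %s: enriched set %s not contiguous, mapped to %s",
                cluster_id, sorted(enriched), cat.value,
            )
        cat_by_cluster[int(cluster_id)] = cat
    assignment.categories = cat_by_cluster
    return assignment.labels.map(cat_by_cluster).rename("category")


def classify_genes(
    profile: StageProfile,
    k: int = 7,
    mode: str = "mean",
    theta: float = 0.0,
    rel_enrich: float = 0.5,
) -> pd.DataFrame:
    """Full classification: exclude unexpressed genes, cluster, categorize.

    Parameters
    ----------
    profile
        Aggregated stage profile of all genes.
    k
        Number of clusters to cut the dendrogram into.
    mode
        "mean" clusters mean log2(CPM+1) rows; "pct" clusters the
        percent-expressing rows (robustness variant).
    theta
        Enrichment threshold on the scaled centroid.

    Returns
    -------
    DataFrame indexed by gene_id with columns category (StageCategory),
    rank (nullable Int64) and cluster_id (0 marks NOT_EXPRESSED genes).
    """
    if mode not in ("mean", "pct"):
        raise ValueError(f"mode must be 'mean' or 'pct', got {mode!r}")
    values = profile.mean_expr if mode == "mean" else profile.pct_expr
    expressed = (values > 0).any(axis=1)

    out = pd.DataFrame(
        {
            "category": StageCategory.NOT_EXPRESSED,
            "rank": pd.array([pd.NA] * len(values), dtype="Int64"),
            "cluster_id": 0,
        },
        index=values.index,
    )
    n_expr = int(expressed.sum())
    if n_expr == 0:
        return out
    k_eff = min(k, n_expr)
    if k_eff < k:
        log.warning("only %d expressed genes; cutting tree at k=%d", n_expr, k_eff)

    scaled = scale_rows(values.loc[expressed])
    assignment = cluster_stages(scaled, k=k_eff)
    cats = assign_categories(assignment, theta=theta, rel_enrich=rel_enrich)
    out.loc[cats.index, "category"] = cats
    out.loc[cats.index, "rank"] = pd.array(
        [c.rank for c in cats], dtype="Int64"
    )
    out.loc[assignment.labels.index, "cluster_id"] = assignment.labels
    return out.loc[values.index]


def categorize_by_pct(
    profile: StageProfile, k: int = 7, theta: float = 0.0
) -> pd.DataFrame:
    """Robustness variant: classify from percent-expressing profiles."""
    return classify_genes(profile, k=k, mode="pct", theta=theta)


def agreement_rate(categories_a: pd.Series, categories_b: pd.Series) -> float:
    """Fraction of shared genes assigned the same category by two runs."""
    common = categories_a.index.intersection(categories_b.index)
    if len(common) == 0:
        raise ValueError("no shared genes between the two category sets")
    return float((categories_a[common] == categories_b[common]).mean())
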