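"""Stage-shift scoring between parental and new genes.

Each parental/new ("child") gene pair is scored by the difference of the
child's and parent's stage ranks (1 = mitosis ... 4 = meiosis/postmeiosis);
a positive shift means the new gene is expressed later in spermatogenesis.
Pairs crossing the mitotic/meiotic boundary are classified "into the
meiosis" (parent rank 1-2, child rank 3-4) or "into the mitosis" (the
reverse); pairs staying on one side are "within" that compartment.  The
module also computes non-overlap percentages (pairs expressed in disjoint
cell-type sets) and Fisher composition comparisons between gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import AUTOSOMES, CHROMOSOMES, StageCategory

log = logging.getLogger(__name__)

MECHANISMS = ("DNA", "RNA", "DENOVO")
ROUTES = ("AtoA_intra", "AtoA_inter", "AtoX", "XtoA", "XtoX", "other")

INTO_MEIOSIS = "into_meiosis"
INTO_MITOSIS = "into_mitosis"
WITHIN_MITOTIC = "within_mitotic"
WITHIN_MEIOTIC = "within_meiotic"
UNCLASSIFIED = "unclassified"
DIRECTIONS = (INTO_MEIOSIS, INTO_MITOSIS, WITHIN_MITOTIC, WITHIN_MEIOTIC)


@dataclass
class ShiftRecord:
    child_id: str
    parent_id: str | None
    branch: int
    mechanism: str
    route: str | None
    parent_rank: int | None
    child_rank: int | None
    shift: int | None
    direction: str


def derive_route(parent_chrom: str | None, child_chrom: str) -> str | None:
    """Chromosomal route of a duplication; None for de novo (no parent).

    "XtoA" iff the parent is X-linked and the child on a major autosome
    (2L/2R/3L/3R); movements touching the dot or Y chromosome are "other".
    """
    if parent_chrom is None:
        return None
    for chrom in (parent_chrom, child_chrom):
        if chrom not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {chrom!r}")
    p_auto = parent_chrom in AUTOSOMES
    c_auto = child_chrom in AUTOSOMES
    if p_auto and c_auto:
        return "AtoA_intra" if parent_chrom == child_chrom else "AtoA_inter"
    if p_auto and child_chrom == "X":
        return "AtoX"
    if parent_chrom == "X" and c_auto:
        return "XtoA"
    if parent_chrom == "X" and child_chrom == "X":
        return "XtoX"
    return "other"


def shift_score(parent_rank: int, child_rank: int) -> int:
    """Stage shift = child rank - parent rank, in -3..3."""
    for r in (parent_rank, child_rank):
        if r not in (1, 2, 3, 4):
            raise ValueError(f"rank must be in 1..4, got {r}")
    return child_rank - parent_rank


def classify_shift(parent_rank: int, child_rank: int) -> str:
    """Directional class of a rank pair; a partition of the 16 pairs.

    The mitotic compartment is ranks {1, 2}, the meiotic compartment ranks
    {3, 4}.  Crossing mitotic -> meiotic is "into the meiosis", the reverse
    "into the mitosis"; pairs staying within one compartment are
    "within_mitotic" / "within_meiotic".
    """
    shift_score(parent_rank, child_rank)  # validate ranks
    p_mit = parent_rank <= 2
    c_mit = child_rank <= 2
    if p_mit and not c_mit:
        return INTO_MEIOSIS
    if not p_mit and c_mit:
        return INTO_MITOSIS
    return WITHIN_MITOTIC if p_mit else WITHIN_MEIOTIC


def load_pairs(pair_table: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate a new-gene table and derive each pair's route.

    ``pair_table`` columns: child_id, parent_id (empty/NaN for de novo),
    branch (1-6), mechanism (DNA/RNA/DENOVO).  Chromosomes are looked up in
    ``annotations`` (gene_id, chromosome).
    """
    annot = annotations
    if "gene_id" in annot.columns:
        annot = annot.set_index("gene_id")
    chrom = annot["chromosome"]

    df = pair_table.copy()
    df["parent_id"] = df["parent_id"].replace({"": None, np.nan: None})
    bad_mech = set(df["mechanism"]) - set(MECHANISMS)
    if bad_mech:
        raise ValueError(f"unknown mechanism(s): {sorted(bad_mech)}")
    denovo = df["mechanism"] == "DENOVO"
    if (df.loc[denovo, "parent_id"].notna()).any():
        raise ValueError("DENOVO pairs must have an empty parent_id")
    if (df.loc[~denovo, "parent_id"].isna()).any():
        raise ValueError("duplication pairs must name a parent_id")
    if not df["branch"].isin(range(1, 7)).all():
        raise ValueError("branch must be an integer in 1..6")

    df["route"] = [
        derive_route(None if p is None else chrom[p], chrom[c])
        for p, c in zip(df["parent_id"], df["child_id"])
    ]
    return df


def score_pairs(pairs: pd.DataFrame, categories: pd.Series) -> pd.DataFrame:
    """Build shift records: ranks, shift and direction for every pair.

    Pairs with an unexpressed (or uncategorized) member get no score and
    direction "unclassified"; they are kept so composition plots can show a
    not-expressed slice.
    """
    ranks = categories.map(lambda c: c.rank)

    def _rank(gene_id: str | None) -> int | None:
        if gene_id is None or gene_id not in ranks.index:
            return None
        r = ranks[gene_id]
        return None if pd.isna(r) else int(r)

    rows = []
    for rec in pairs.itertuples(index=False):
        p_rank = _rank(rec.parent_id)
        c_rank = _rank(rec.child_id)
        if p_rank is None or c_rank is None:
            shift, direction = None, UNCLASSIFIED
        else:
            shift = shift_score(p_rank, c_rank)
            direction = classify_shift(p_rank, c_rank)
        rows.append(
            {
                "child_id": rec.child_id,
                "parent_id": rec.parent_id,
                "branch": rec.branch,
                "mechanism": rec.mechanism,
                "route": rec.route,
                "parent_rank": p_rank,
                "child_rank": c_rank,
                "shift": shift,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows)
    for col in ("parent_rank", "child_rank", "shift"):
        out[col] = pd.array(out[col], dtype="Int64")
    return out


def nonoverlap_fraction(
    pairs: pd.DataFrame, categories: pd.Series, by: str | list[str] = "branch"
) -> pd.Series:
    """Percent of expressed pairs whose cell-type sets are disjoint.

    Each expressed category maps to its cell-type set; a pair counts as
    non-overlapping iff the parent's and child's sets do not intersect.
    Fractions are taken over the pairs of each stratum in which both genes
    are expressed; strata with no eligible pair yield NaN.
    """
    sets = categories.map(lambda c: c.cell_set)

    def _cells(gene_id):
        if gene_id is None or gene_id not in sets.index:
            return None
        return sets[gene_id]

    df = pairs.copy()
    df["_p"] = df["parent_id"].map(_cells)
    df["_c"] = df["child_id"].map(_cells)
    eligible = df["_p"].notna() & df["_c"].notna()

    def _frac(group: pd.DataFrame) -> float:
        ok = group[group["_p"].notna() & group["_c"].notna()]
        if len(ok) == 0:
            return float("nan")
        disjoint = [len(p & c) == 0 for p, c in zip(ok["_p"], ok["_c"])]
        return 100.0 * float(np.mean(disjoint))

    if not eligible.any():
        log.warning("no pair has both members expressed")
    return df.groupby(by, dropna=False).apply(_frac, include_groups=False).rename(
        "pct_nonoverlap"
    )


def composition_compare(
    cats_a: pd.Series | list,
    cats_b: pd.Series | list,
    pooling: bool = True,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Per-category two-sided Fisher test between two gene sets.

    For each category (meiosis pooled with postmeiosis when ``pooling``),
    the 2x2 table is [[in-cat_a, rest_a], [in-cat_b, rest_b]].  Used for
    child-vs-parent comparisons per stratum and for de novo genes against
    the genomic background.  Raw p plus BH-adjusted q are reported.
    """
    def _names(cats) -> list[str]:
        out = []
        for c in cats:
            name = c.value if isinstance(c, StageCategory) else str(c)
            if pooling and name == "postmeiosis":
                name = "meiosis+postmeiosis"
            elif pooling and name == "meiosis":
                name = "meiosis+postmeiosis"
            out.append(name)
        return out

    a_names, b_names = _names(cats_a), _names(cats_b)
    if not a_names or not b_names:
        raise ValueError("both gene sets must be non-empty")
    universe = sorted(set(a_names) | set(b_names))
    n_a, n_b = len(a_names), len(b_names)
    rows = []
    for cat in universe:
        a = a_names.count(cat)
        c = b_names.count(cat)
        table = [[a, n_a - a], [c, n_b - c]]
        odds, p = fisher_exact(table, alternative="two-sided")
        direction = "enriched" if odds > 1 else ("depleted" if odds < 1 else None)
        rows.append(
            {
                "category": cat,
                f"in_{labels[0]}": a, f"rest_{labels[0]}": n_a - a,
                f"in_{labels[1]}": c, f"rest_{labels[1]}": n_b - c,
                "odds_ratio": float(odds), "p": float(p),
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def compare_strata(
    records: pd.DataFrame,
    categories: pd.Series,
    by: str | list[str] = "route",
) -> dict[str, pd.DataFrame]:
    """Child-vs-parent composition comparison within each stratum.

    De novo children (no parent) are skipped here; compare them against the
    genomic background with :func:`composition_compare` directly.  Empty
    strata are skipped with a log entry.
    """
    results: dict[str, pd.DataFrame] = {}
    for key, group in records.groupby(by, dropna=False):
        dup = group[group["parent_id"].notna()]
        if len(dup) == 0:
            log.info("stratum %s: no duplication pairs, skipped", key)
            continue
        child_cats = [categories[g] for g in dup["child_id"] if g in categories.index]
        parent_cats = [categories[g] for g in dup["parent_id"] if g in categories.index]
        if not child_cats or not parent_cats:
            log.info("stratum %s: no categorized genes, skipped", key)
            continue
        name = key if isinstance(key, str) else "_".join(map(str, key))
        results[name] = composition_compare(
            child_cats, parent_cats, labels=("child", "parent")
        )
    return results


def pair_expression_table(pairs: pd.DataFrame, profile) -> pd.DataFrame:
    """Long-form expression table for plotting parent/child pairs.

    One row per (pair, gene, cell type) with the mean log2(CPM+1) and the
    percent of expressing cells — the data behind bubble plots of
    individual parental/new gene cases.  Genes absent from the profile are
    skipped.
    """
    rows = []
    for rec in pairs.itertuples(index=False):
        for role, gid in (("parent", rec.parent_id), ("child", rec.child_id)):
            if gid is None or gid not in profile.gene_ids:
                continue
            for ct in profile.mean_expr.columns:
                rows.append(
                    {
                        "child_id": rec.child_id,
                        "gene_id": gid,
                        "role": role,
                        "cell_type": ct,
                        "mean_log2cpm": profile.mean_expr.loc[gid, ct],
                        "pct_expressing": profile.pct_expr.loc[gid, ct],
                    }
                )
    return pd.DataFrame(rows)


def shift_spectrum(
    records: pd.DataFrame, by: str | list[str] = ("route", "mechanism")
) -> pd.DataFrame:
    """Per-stratum shift histogram and direction percentages.

    For each stratum: counts of shift values -3..3 over scored pairs, the
    number of scored and unscored pairs, and the percentage of each
    directional class among scored pairs (the four percentages sum to 100).
    """
    by = list(by) if not isinstance(by, str) else [by]
    rows = []
    for key, group in records.groupby(by, dropna=False):
        scored = group[group["shift"].notna()]
        row: dict = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_pairs"] = len(group)
        row["n_scored"] = len(scored)
        for s in range(-3, 4):
            row[f"shift_{s}"] = int((scored["shift"] == s).sum())
        for d in DIRECTIONS:
            row[f"pct_{d}"] = (
                100.0 * float((scored["direction"] == d).mean())
                if len(scored) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
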