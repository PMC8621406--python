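"""Inter-chromosomal retrogene movement against a null expectation.

Under a null with no chromosomal preference, the number of duplications
from source chromosome i to target chromosome j is proportional to the
number of parental genes on i and to the physical size of j:
``E[i->j] = N * (g_i / sum g) * (L_j / sum L)``.  Comparing observed
retroposition counts with this expectation tests the "out of the X"
pattern — an excess of X-linked parents producing autosomal retrogenes,
expected under meiotic sex chromosome inactivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .core import AUTOSOMES

log = logging.getLogger(__name__)


@dataclass
class TrafficTable:
    """Observed and expected source x target movement counts with a test."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    N: int
    g: pd.Series
    L: pd.Series
    chi2: float | None = None
    df: int | None = None
    p: float | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"N": self.N, "chi2": self.chi2, "df": self.df, "p": self.p}]
        )


def expected_traffic(
    N: int,
    g: pd.Series,
    L: pd.Series,
    exclude_intra: bool = True,
) -> pd.DataFrame:
    """Expected source x target counts under the gene-number x size null.

    Parameters
    ----------
    N
        Total number of movements (pairs).
    g
        Parental gene count per chromosome (source propensity).
    L
        Chromosome length in bp (target propensity).
    exclude_intra
        Zero the diagonal and renormalize each row over the remaining
        targets, preserving row totals — retroposition is analyzed as an
        inter-chromosomal process.

    The matrix sums to N, scales linearly in N, and is invariant to a
    common rescaling of g or of L.
    """
    chroms = list(g.index)
    if list(L.index) != chroms:
        L = L.reindex(chroms)
    if g.isna().any() or L.isna().any() or (g <= 0).any() or (L <= 0).any():
        raise ValueError("g and L must be positive on every chromosome considered")
    src = g / g.sum()
    tgt = L / L.sum()
    exp = np.outer(src, tgt) * N
    exp = pd.DataFrame(exp, index=chroms, columns=chroms)
    if exclude_intra:
        for c in chroms:
            row_total = exp.loc[c].sum()
            exp.loc[c, c] = 0.0
            remaining = exp.loc[c].sum()
            if remaining > 0:
                exp.loc[c] *= row_total / remaining
    exp.index.name = "source"
    exp.columns.name = "target"
    return exp


def observed_traffic(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    mechanism: str | None = "RNA",
    chroms: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Observed source x target counts from a routed pair table.

    Defaults to RNA-based (retroposed) duplications; intra-chromosomal
    pairs land on the diagonal and are typically excluded by the test's
    expected matrix.
    """
    annot = annotations
    if "gene_id" in annot.columns:
        annot = annot.set_index("gene_id")
    chrom = annot["chromosome"]
    df = pairs[pairs["parent_id"].notna()]
    if mechanism is not None:
        df = df[df["mechanism"] == mechanism]
    src = df["parent_id"].map(chrom)
    tgt = df["child_id"].map(chrom)
    if chroms is None:
        chroms = tuple(sorted(set(src) | set(tgt)))
    obs = pd.DataFrame(0, index=list(chroms), columns=list(chroms))
    for s, t in zip(src, tgt):
        if s in obs.index and t in obs.columns:
            obs.loc[s, t] += 1
    obs.index.name = "source"
    obs.columns.name = "target"
    return obs


def default_grouping(chroms: list[str]) -> dict[str, list[tuple[str, str]]]:
    """Two classes over inter-chromosomal cells: X->A versus everything else."""
    x_to_a, other = [], []
    for s in chroms:
        for t in chroms:
            if s == t:
                continue
            if s == "X" and t in AUTOSOMES:
                x_to_a.append((s, t))
            else:
                other.append((s, t))
    return {"XtoA": x_to_a, "other": other}


def out_of_x_test(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    grouping: dict[str, list[tuple[str, str]]] | None = None,
    continuity: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square on collapsed movement classes.

    Cells of the observed and expected matrices are summed within each
    class of ``grouping`` (default: X->A movements vs all other
    inter-chromosomal movements) and the plain chi-square
    ``sum (O-E)^2 / E`` is computed with ``df = classes - 1``.  A Yates
    continuity correction is available but off by default.
    """
    if grouping is None:
        grouping = default_grouping(list(observed.index))
    if len(grouping) < 2:
        raise ValueError("grouping must collapse cells into at least 2 classes")
    obs = np.array(
        [sum(observed.loc[s, t] for s, t in cells) for cells in grouping.values()],
        dtype=float,
    )
    exp = np.array(
        [sum(expected.loc[s, t] for s, t in cells) for cells in grouping.values()],
        dtype=float,
    )
    if (exp < 1).any():
        log.warning("collapsed expected count < 1; chi-square unreliable")
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive in every class")
    dev = np.abs(obs - exp)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / exp).sum())
    df = len(grouping) - 1
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def traffic_analysis(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    chrom_lengths: pd.Series,
    mechanism: str | None = "RNA",
    exclude_intra: bool = True,
) -> TrafficTable:
    """End-to-end movement analysis: observed, expected, out-of-X test."""
    annot = annotations
    if "gene_id" in annot.columns:
        annot = annot.set_index("gene_id")
    chroms = [c for c in chrom_lengths.index if c in set(annot["chromosome"])]
    obs = observed_traffic(pairs, annot, mechanism=mechanism, chroms=tuple(chroms))
    N = int(obs.to_numpy().sum() - (0 if not exclude_intra else np.trace(obs)))
    # source propensity: parental gene count per chromosome in the annotation
    g = annot["chromosome"].value_counts().reindex(chroms)
    L = chrom_lengths.reindex(chroms)
    exp = expected_traffic(N, g, L, exclude_intra=exclude_intra)
    if exclude_intra:
        obs = obs.copy()
        for c in obs.index:
            obs.loc[c, c] = 0
    chi2, df, p = out_of_x_test(obs, exp)
    return TrafficTable(
        observed=obs, expected=exp, N=N, g=g, L=L, chi2=chi2, df=df, p=p
    )
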