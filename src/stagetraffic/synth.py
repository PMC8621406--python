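"""Synthetic testis single-cell data with planted stage archetypes.

The generator emulates the shape of the real inputs — a germline-labeled
cell x gene UMI matrix, a gene annotation table and a parental/new gene
table — with known ground truth, so the whole pipeline can be exercised
and its recovery quantified without any download.  Genes follow one of
five stage-archetype expression programs over the four germline cell types
(plus a not-expressed class); counts are drawn from a negative binomial
around the program scaled to a target library size; parental/new pairs are
planted per (route, mechanism) stratum with a configurable probability
that the child's stage is shifted above its parent's ("into the meiosis").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .core import AUTOSOMES, CHROMOSOMES, StageCategory
from .ingest import LabeledCounts

ARCHETYPE_NAMES = (
    "MITOSIS",
    "MITOSIS_MEIOSIS",
    "MEIOSIS",
    "MEIOSIS_POSTMEIOSIS",
    "POSTMEIOSIS",
    "NOT_EXPRESSED",
)

#: Relative expression program of each archetype over
#: (spermatogonia, early spermatocytes, late spermatocytes, spermatids).
#: Only the rank structure matters downstream: each program is maximal
#: exactly on the cell types its archetype names.
ARCHETYPE_PROGRAMS: dict[str, tuple[float, float, float, float]] = {
    "MITOSIS": (1.0, 0.1, 0.05, 0.05),
    "MITOSIS_MEIOSIS": (1.0, 1.0, 0.1, 0.05),
    "MEIOSIS": (0.05, 1.0, 1.0, 0.1),
    "MEIOSIS_POSTMEIOSIS": (0.05, 0.1, 1.0, 1.0),
    "POSTMEIOSIS": (0.05, 0.05, 0.1, 1.0),
    "NOT_EXPRESSED": (0.0, 0.0, 0.0, 0.0),
}

#: Archetype of each stage rank; rank 4 covers two archetypes.
RANK_TO_ARCHETYPES: dict[int, tuple[str, ...]] = {
    1: ("MITOSIS",),
    2: ("MITOSIS_MEIOSIS",),
    3: ("MEIOSIS",),
    4: ("MEIOSIS_POSTMEIOSIS", "POSTMEIOSIS"),
}

ARCHETYPE_RANK: dict[str, int] = {
    "MITOSIS": 1,
    "MITOSIS_MEIOSIS": 2,
    "MEIOSIS": 3,
    "MEIOSIS_POSTMEIOSIS": 4,
    "POSTMEIOSIS": 4,
}

ARCHETYPE_TO_CATEGORY: dict[str, StageCategory] = {
    name: StageCategory[name] for name in ARCHETYPE_NAMES
}

_DEFAULT_CHROM_PROPS = {
    # roughly the arm share of genes in the D. melanogaster genome; the Y
    # is gene-poor and the dot chromosome tiny
    "2L": 0.19, "2R": 0.21, "3L": 0.19, "3R": 0.22, "4": 0.01, "X": 0.16, "Y": 0.02,
}

_INTER_STRATA = (
    ("AtoA_inter", "DNA"), ("AtoA_inter", "RNA"),
    ("AtoX", "DNA"), ("AtoX", "RNA"),
    ("XtoA", "DNA"), ("XtoA", "RNA"),
)

#: Default pair counts: every inter-chromosomal (route, mechanism) stratum,
#: plus intra-chromosomal DNA duplications and de novo genes.
_DEFAULT_PAIRS = {s: 100 for s in _INTER_STRATA}
_DEFAULT_PAIRS[("AtoA_intra", "DNA")] = 100
_DEFAULT_PAIRS[("DENOVO", "DENOVO")] = 100

#: Default planted probability that a child is shifted above its parent:
#: a background of 0.3 everywhere, raised to 0.6 for X->A retroposition —
#: the out-of-the-X / into-the-meiosis signal the analysis must detect.
_DEFAULT_P_INTO = {"default": 0.3, ("XtoA", "RNA"): 0.6}

#: Parents are drawn mostly from mitotic archetypes, as the progenitors of
#: testis new genes predominantly are.
_DEFAULT_PARENT_WEIGHTS = {
    "MITOSIS": 0.5,
    "MITOSIS_MEIOSIS": 0.2,
    "MEIOSIS": 0.2,
    "MEIOSIS_POSTMEIOSIS": 0.05,
    "POSTMEIOSIS": 0.05,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic universe.

    Attributes
    ----------
    n_genes_per_archetype
        Genes generated per archetype (the five programs plus NOT_EXPRESSED).
    cells_per_type
        Cells simulated per germline cell type.
    depth_mean
        Mean library size (total UMI counts per cell).
    noise_dispersion
        Negative-binomial dispersion alpha >= 0 (variance = mu + alpha mu^2);
        0 gives Poisson counts.
    chrom_props
        Probability of each chromosome when assigning genes.
    n_pairs_by_route_mech
        Pairs to generate per (route, mechanism) stratum; the key
        ("DENOVO", "DENOVO") generates de novo genes.
    p_into_meiosis
        Per (route, mechanism) probability that the child archetype is
        planted at least one rank above its parent's; the "default" key
        covers unlisted strata.
    parent_archetype_weights
        Sampling weights of parental archetypes.
    seed
        Master seed; identical seed and config give identical outputs.
    """

    n_genes_per_archetype: int = 100
    cells_per_type: int = 100
    depth_mean: float = 5000.0
    noise_dispersion: float = 0.3
    chrom_props: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_PROPS)
    )
    n_pairs_by_route_mech: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_PAIRS)
    )
    p_into_meiosis: dict = field(default_factory=lambda: dict(_DEFAULT_P_INTO))
    parent_archetype_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PARENT_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        # accept "route:mechanism" string keys (the YAML form) transparently
        self.n_pairs_by_route_mech = {
            (tuple(k.split(":")) if isinstance(k, str) else tuple(k)): int(v)
            for k, v in self.n_pairs_by_route_mech.items()
        }
        self.p_into_meiosis = {
            (k if k == "default" else
             (tuple(k.split(":")) if isinstance(k, str) else tuple(k))): float(v)
            for k, v in self.p_into_meiosis.items()
        }
        probs = np.array([self.chrom_props.get(c, 0.0) for c in CHROMOSOMES])
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("chrom_props must be a probability vector over "
                             f"{CHROMOSOMES} summing to 1")
        if self.n_genes_per_archetype < 0 or self.cells_per_type < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if any(n < 0 for n in self.n_pairs_by_route_mech.values()):
            raise ValueError("pair counts must be >= 0")

    def p_shift(self, route: str, mechanism: str) -> float:
        return float(
            self.p_into_meiosis.get(
                (route, mechanism), self.p_into_meiosis.get("default", 0.0)
            )
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["n_pairs_by_route_mech"] = {
            f"{r}:{m}": n for (r, m), n in self.n_pairs_by_route_mech.items()
        }
        d["p_into_meiosis"] = {
            (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): v
            for k, v in self.p_into_meiosis.items()
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SynthConfig":
        d = yaml.safe_load(text)
        if "n_pairs_by_route_mech" in d:
            d["n_pairs_by_route_mech"] = {
                tuple(k.split(":")): int(v)
                for k, v in d["n_pairs_by_route_mech"].items()
            }
        if "p_into_meiosis" in d:
            d["p_into_meiosis"] = {
                (k if k == "default" else tuple(k.split(":"))): float(v)
                for k, v in d["p_into_meiosis"].items()
            }
        return cls(**d)


def generate_universe(config: SynthConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Annotated gene universe with true archetype labels.

    Returns a (annotation table, labels) pair: the table has one row per
    gene (gene_id, chromosome, length, exon_count) and the labels series
    records each gene's planted archetype for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, chroms, labels = [], [], []
    probs = np.array([config.chrom_props.get(c, 0.0) for c in CHROMOSOMES])
    for arch in ARCHETYPE_NAMES:
        for i in range(config.n_genes_per_archetype):
            gene_ids.append(f"g_{arch.lower()}_{i:04d}")
            labels.append(arch)
    n = len(gene_ids)
    chroms = rng.choice(CHROMOSOMES, size=n, p=probs)
    lengths = rng.integers(500, 20000, size=n)
    exons = rng.integers(1, 12, size=n)
    annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chroms,
            "length": lengths,
            "exon_count": exons,
        }
    )
    labels = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="archetype")
    return annot, labels


def generate_counts(
    labels: pd.Series, config: SynthConfig
) -> LabeledCounts:
    """Cell x gene counts drawn around the archetype programs.

    Within each cell type, per-gene means are the archetype program values
    normalized over genes and scaled to ``depth_mean``; counts are negative
    binomial with dispersion ``noise_dispersion`` (Poisson at 0).
    NOT_EXPRESSED genes yield all-zero columns.
    """
    if config.cells_per_type <= 0:
        raise ValueError("cells_per_type must be positive to generate counts")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids = np.asarray(labels.index, dtype=object)
    programs = np.array([ARCHETYPE_PROGRAMS[a] for a in labels])  # genes x 4

    from .core import CELL_TYPES

    blocks, cell_types, cell_ids = [], [], []
    for t_idx, ct in enumerate(CELL_TYPES):
        rel = programs[:, t_idx]
        total = rel.sum()
        mu = (
            np.zeros_like(rel)
            if total == 0
            else config.depth_mean * rel / total
        )
        n_cells = config.cells_per_type
        mu_mat = np.tile(mu, (n_cells, 1))
        if config.noise_dispersion == 0:
            counts = rng.poisson(mu_mat)
        else:
            shape = 1.0 / config.noise_dispersion
            lam = np.where(
                mu_mat > 0,
                rng.gamma(shape, 1.0, size=mu_mat.shape) * mu_mat / shape,
                0.0,
            )
            counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        cell_types.extend([ct] * n_cells)
        cell_ids.extend([f"{ct}_{i:04d}" for i in range(n_cells)])
    return LabeledCounts(
        counts=sp.vstack(blocks, format="csr"),
        cell_types=np.array(cell_types, dtype=object),
        gene_ids=gene_ids,
        cell_ids=np.array(cell_ids, dtype=object),
    )


def _route_chroms(route: str, rng: np.random.Generator) -> tuple[str | None, str]:
    """Sample (parent, child) chromosomes consistent with a route."""
    A = sorted(AUTOSOMES)
    if route == "AtoA_intra":
        c = rng.choice(A)
        return c, c
    if route == "AtoA_inter":
        p = rng.choice(A)
        c = rng.choice([a for a in A if a != p])
        return p, c
    if route == "AtoX":
        return rng.choice(A), "X"
    if route == "XtoA":
        return "X", rng.choice(A)
    if route == "XtoX":
        return "X", "X"
    raise ValueError(f"cannot sample chromosomes for route {route!r}")


def generate_pairs(
    annotations: pd.DataFrame,
    labels: pd.Series,
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Plant parental/new gene pairs with route-dependent stage shifts.

    Parents are sampled (with replacement) from the universe's genes on the
    route's source chromosome, restricted to expressed archetypes weighted
    by ``parent_archetype_weights``.  Each child is a newly created gene on
    the route's target chromosome; with probability ``p_into_meiosis`` for
    its (route, mechanism) the child's archetype is planted uniformly among
    ranks strictly above the parent's (parents at rank 4 are resampled from
    ranks 1-3 when a shift is planted), otherwise the child inherits the
    parent's archetype.  De novo children get their own archetype drawn
    from the parent weights and no parent.

    Returns (pair table, augmented annotations, augmented labels); run
    :func:`generate_counts` on the augmented labels so the children have
    expression too.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    annot = annotations.set_index("gene_id")
    weights = config.parent_archetype_weights
    arch_names = [a for a in weights if weights[a] > 0]
    w = np.array([weights[a] for a in arch_names], dtype=float)
    w = w / w.sum()

    by_chrom_arch: dict[tuple[str, str], list[str]] = {}
    for gid, arch in labels.items():
        by_chrom_arch.setdefault((annot.loc[gid, "chromosome"], arch), []).append(gid)

    new_rows, new_labels, pair_rows = [], {}, []
    counter = 0
    for (route, mech), n in sorted(config.n_pairs_by_route_mech.items()):
        if n == 0:
            continue
        if route == "DENOVO":
            for _ in range(n):
                counter += 1
                arch = rng.choice(arch_names, p=w)
                chrom = rng.choice(
                    CHROMOSOMES,
                    p=np.array([config.chrom_props.get(c, 0.0) for c in CHROMOSOMES]),
                )
                child = f"dn_{counter:05d}"
                new_rows.append(
                    {"gene_id": child, "chromosome": chrom,
                     "length": int(rng.integers(300, 3000)), "exon_count": 1}
                )
                new_labels[child] = arch
                pair_rows.append(
                    {"child_id": child, "parent_id": None,
                     "branch": int(rng.integers(1, 7)), "mechanism": "DENOVO"}
                )
            continue

        p_shift = config.p_shift(route, mech)
        for _ in range(n):
            counter += 1
            parent_chrom, child_chrom = _route_chroms(route, rng)
            shifted = bool(rng.random() < p_shift)
            # when a shift is planted the parent must leave room above
            allowed = [
                a for a in arch_names
                if not (shifted and ARCHETYPE_RANK[a] >= 4)
            ]
            wa = np.array([weights[a] for a in allowed], dtype=float)
            wa = wa / wa.sum()
            parent_arch = None
            candidates: list[str] = []
            for _attempt in range(50):
                arch = rng.choice(allowed, p=wa)
                candidates = by_chrom_arch.get((parent_chrom, arch), [])
                if candidates:
                    parent_arch = arch
                    break
            if parent_arch is None:
                raise RuntimeError(
                    f"cannot sample a parent on {parent_chrom} for stratum "
                    f"({route}, {mech}): no gene of any allowed archetype"
                )
            parent = candidates[rng.integers(len(candidates))]
            p_rank = ARCHETYPE_RANK[parent_arch]
            if shifted:
                c_rank = int(rng.integers(p_rank + 1, 5))
                opts = RANK_TO_ARCHETYPES[c_rank]
                child_arch = opts[rng.integers(len(opts))]
            else:
                child_arch = parent_arch
            child = f"nc_{counter:05d}"
            new_rows.append(
                {"gene_id": child, "chromosome": child_chrom,
                 "length": int(rng.integers(300, 5000)),
                 "exon_count": 1 if mech == "RNA" else int(rng.integers(1, 12))}
            )
            new_labels[child] = child_arch
            pair_rows.append(
                {"child_id": child, "parent_id": parent,
                 "branch": int(rng.integers(1, 7)), "mechanism": mech}
            )

    pair_table = pd.DataFrame(
        pair_rows, columns=["child_id", "parent_id", "branch", "mechanism"]
    )
    aug_annot = pd.concat(
        [annotations, pd.DataFrame(new_rows)], ignore_index=True
    )
    aug_labels = pd.concat(
        [
            labels,
            pd.Series(new_labels, name="archetype").rename_axis("gene_id"),
        ]
    ).rename("archetype")
    return pair_table, aug_annot, aug_labels
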