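"""Shared vocabulary of the spermatogenesis stage analysis.

Spermatogenesis proceeds through four germline cell types — spermatogonia
(mitotic), early and late spermatocytes (meiotic) and spermatids
(post-meiotic).  Genes are assigned one of five expressed stage categories
according to the cell types in which they are predominantly expressed, plus
an explicit NOT_EXPRESSED category; the four expressed stages carry an
ordinal rank 1-4 used to score parent/new-gene stage shifts.
"""

from __future__ import annotations

import enum

#: The four germline cell types, in developmental order.
CELL_TYPES: tuple[str, ...] = (
    "spermatogonia",
    "early_spermatocytes",
    "late_spermatocytes",
    "spermatids",
)

#: Chromosome arms of the D. melanogaster assembly considered here.
CHROMOSOMES: tuple[str, ...] = ("2L", "2R", "3L", "3R", "4", "X", "Y")

#: The major autosomes; excludes the dot chromosome (4), an ancient former X
#: that shares the regulatory behaviour of the X in the male germline.
AUTOSOMES: frozenset[str] = frozenset({"2L", "2R", "3L", "3R"})


class StageCategory(enum.Enum):
    """Developmental stage category of a gene in the testis.

    The four expressed germline stages are ordered 1-4 from mitosis to
    post-meiosis.  Genes predominantly expressed in spermatids
    (POSTMEIOSIS) are pooled with MEIOSIS_POSTMEIOSIS at rank 4 for shift
    scoring, because post-meiotic genes are few and downstream tests merge
    the meiotic and post-meiotic stages.
    """

    NOT_EXPRESSED = "not_expressed"
    MITOSIS = "mitosis"
    MITOSIS_MEIOSIS = "mitosis_meiosis"
    MEIOSIS = "meiosis"
    MEIOSIS_POSTMEIOSIS = "meiosis_postmeiosis"
    POSTMEIOSIS = "postmeiosis"

    @property
    def rank(self) -> int | None:
        """Ordinal stage rank in 1..4, or None for NOT_EXPRESSED."""
        return _RANKS[self]

    @property
    def cell_set(self) -> frozenset[str] | None:
        """Cell types in which genes of this category are expressed."""
        return _CELL_SETS[self]


_RANKS: dict[StageCategory, int | None] = {
    StageCategory.NOT_EXPRESSED: None,
    StageCategory.MITOSIS: 1,
    StageCategory.MITOSIS_MEIOSIS: 2,
    StageCategory.MEIOSIS: 3,
    StageCategory.MEIOSIS_POSTMEIOSIS: 4,
    StageCategory.POSTMEIOSIS: 4,
}

_CELL_SETS: dict[StageCategory, frozenset[str] | None] = {
    StageCategory.NOT_EXPRESSED: None,
    StageCategory.MITOSIS: frozenset({"spermatogonia"}),
    StageCategory.MITOSIS_MEIOSIS: frozenset(
        {"spermatogonia", "early_spermatocytes"}
    ),
    StageCategory.MEIOSIS: frozenset(
        {"early_spermatocytes", "late_spermatocytes"}
    ),
    StageCategory.MEIOSIS_POSTMEIOSIS: frozenset(
        {"late_spermatocytes", "spermatids"}
    ),
    StageCategory.POSTMEIOSIS: frozenset({"spermatids"}),
}

#: Expressed categories in rank order (POSTMEIOSIS last, sharing rank 4).
EXPRESSED_CATEGORIES: tuple[StageCategory, ...] = (
    StageCategory.MITOSIS,
    StageCategory.MITOSIS_MEIOSIS,
    StageCategory.MEIOSIS,
    StageCategory.MEIOSIS_POSTMEIOSIS,
    StageCategory.POSTMEIOSIS,
)

ALL_CATEGORIES: tuple[StageCategory, ...] = EXPRESSED_CATEGORIES + (
    StageCategory.NOT_EXPRESSED,
)


def category_from_string(value: str) -> StageCategory:
    """Parse a category from its TSV string form (case-insensitive)."""
    try:
        return StageCategory(value.strip().lower())
    except ValueError as exc:
        valid = ", ".join(c.value for c in StageCategory)
        raise ValueError(f"unknown stage category {value!r}; expected one of {valid}") from exc
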