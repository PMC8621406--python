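"""Stage-shift scoring, direction classes, non-overlap and composition."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stagetraffic as st
from stagetraffic.core import StageCategory
from stagetraffic.pairs import (
    DIRECTIONS,
    INTO_MEIOSIS,
    INTO_MITOSIS,
    UNCLASSIFIED,
    WITHIN_MEIOTIC,
    WITHIN_MITOTIC,
    compare_strata,
)

from conftest import fisher_p_enumeration


def rule_table_oracle(parent: int, child: int) -> str:
    """Independent enumeration of the direction rule: crossing the
    mitotic ({1,2}) / meiotic ({3,4}) boundary decides the class."""
    sides = {1: "mit", 2: "mit", 3: "mei", 4: "mei"}
    p, c = sides[parent], sides[child]
    if p == "mit" and c == "mei":
        return INTO_MEIOSIS
    if p == "mei" and c == "mit":
        return INTO_MITOSIS
    return WITHIN_MITOTIC if p == "mit" else WITHIN_MEIOTIC


class TestShiftScore:
    def test_worked_example_mitosis_to_postmeiosis(self):
        assert st.shift_score(1, 4) == 3
        assert st.classify_shift(1, 4) == INTO_MEIOSIS

    @pytest.mark.parametrize("p,c", list(itertools.product(range(1, 5), repeat=2)))
    def test_antisymmetry(self, p, c):
        assert st.shift_score(p, c) == -st.shift_score(c, p)

    def test_identity_and_extremes(self):
        assert st.shift_score(3, 3) == 0
        assert st.shift_score(4, 1) == -3

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            st.shift_score(0, 4)
        with pytest.raises(ValueError):
            st.classify_shift(1, 5)


class TestClassifyShift:
    @pytest.mark.parametrize("p,c", list(itertools.product(range(1, 5), repeat=2)))
    def test_partition_matches_enumeration_oracle(self, p, c):
        assert st.classify_shift(p, c) == rule_table_oracle(p, c)

    def test_all_sixteen_pairs_partitioned(self):
        classes = [
            st.classify_shift(p, c)
            for p, c in itertools.product(range(1, 5), repeat=2)
        ]
        assert set(classes) == set(DIRECTIONS)
        # boundary-crossing sign constraints
        for p, c in itertools.product(range(1, 5), repeat=2):
            d = st.classify_shift(p, c)
            if d == INTO_MEIOSIS:
                assert st.shift_score(p, c) > 0
            if d == INTO_MITOSIS:
                assert st.shift_score(p, c) < 0

    def test_specific_examples(self):
        assert st.classify_shift(2, 1) == WITHIN_MITOTIC
        assert st.classify_shift(4, 2) == INTO_MITOSIS


class TestRoutes:
    @pytest.mark.parametrize(
        "parent,child,route",
        [
            ("X", "2L", "XtoA"), ("X", "3R", "XtoA"),
            ("2L", "X", "AtoX"), ("X", "X", "XtoX"),
            ("2L", "2L", "AtoA_intra"), ("2L", "3R", "AtoA_inter"),
            ("X", "4", "other"), ("Y", "2L", "other"), ("2L", "Y", "other"),
            (None, "2R", None),
        ],
    )
    def test_route_definition(self, parent, child, route):
        assert st.derive_route(parent, child) == route

    def test_route_is_x_to_a_iff_parent_x_child_major_autosome(self):
        for p in st.CHROMOSOMES:
            for c in st.CHROMOSOMES:
                expected = p == "X" and c in st.AUTOSOMES
                assert (st.derive_route(p, c) == "XtoA") == expected


def _toy_scored_pairs():
    cats = pd.Series(
        {
            "p1": StageCategory.MITOSIS,
            "c1": StageCategory.POSTMEIOSIS,
            "p2": StageCategory.MITOSIS_MEIOSIS,
            "c2": StageCategory.MEIOSIS,
            "p3": StageCategory.MEIOSIS,
            "c3": StageCategory.MEIOSIS,
            "p4": StageCategory.NOT_EXPRESSED,
            "c4": StageCategory.MITOSIS,
        }
    )
    cats.index.name = "gene_id"
    pairs = pd.DataFrame(
        {
            "child_id": ["c1", "c2", "c3", "c4"],
            "parent_id": ["p1", "p2", "p3", "p4"],
            "branch": [1, 2, 3, 4],
            "mechanism": ["RNA", "DNA", "DNA", "DNA"],
            "route": ["XtoA", "AtoA_intra", "AtoA_inter", "AtoX"],
        }
    )
    return pairs, cats


class TestScorePairs:
    def test_records_and_unclassified(self):
        pairs, cats = _toy_scored_pairs()
        rec = st.score_pairs(pairs, cats)
        assert rec.loc[0, "shift"] == 3
        assert rec.loc[0, "direction"] == INTO_MEIOSIS
        assert rec.loc[1, "shift"] == 1
        assert rec.loc[2, "shift"] == 0
        assert rec.loc[3, "direction"] == UNCLASSIFIED
        assert pd.isna(rec.loc[3, "shift"])


class TestNonoverlap:
    def test_disjoint_and_shared_cellsets(self):
        pairs, cats = _toy_scored_pairs()
        frac = st.nonoverlap_fraction(pairs, cats, by="branch")
        # branch 1: mitosis {SPG} vs postmeiosis {SPT} -> disjoint
        assert frac[1] == pytest.approx(100.0)
        # branch 2: mitosis_meiosis and meiosis share early spermatocytes
        assert frac[2] == pytest.approx(0.0)
        # branch 4: parent unexpressed -> no eligible pair
        assert np.isnan(frac[4])

    def test_identical_categories_fully_overlap(self):
        cats = pd.Series(
            {f"g{i}": StageCategory.MEIOSIS for i in range(10)}
        )
        cats.index.name = "gene_id"
        pairs = pd.DataFrame(
            {
                "child_id": [f"g{i}" for i in range(5)],
                "parent_id": [f"g{i+5}" for i in range(5)],
                "branch": [1] * 5,
                "mechanism": ["DNA"] * 5,
                "route": ["AtoA_intra"] * 5,
            }
        )
        frac = st.nonoverlap_fraction(pairs, cats, by="branch")
        assert frac[1] == pytest.approx(0.0)


class TestCompositionCompare:
    def test_identical_sets_all_p_one(self):
        cats = [StageCategory.MITOSIS] * 10 + [StageCategory.MEIOSIS] * 5
        out = st.composition_compare(cats, list(cats))
        assert np.allclose(out["p"], 1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        pool = [
            StageCategory.MITOSIS,
            StageCategory.MEIOSIS,
            StageCategory.POSTMEIOSIS,
        ]
        a = list(rng.choice(pool, size=40))
        b = list(rng.choice(pool, size=60))
        out = st.composition_compare(a, b)
        for row in out.itertuples(index=False):
            assert row.p == pytest.approx(
                fisher_p_enumeration(row.in_a, row.rest_a, row.in_b, row.rest_b),
                rel=1e-9,
            )

    def test_meiotic_pooling(self):
        a = [StageCategory.MEIOSIS] * 3 + [StageCategory.POSTMEIOSIS] * 2
        out = st.composition_compare(a, a)
        assert "meiosis+postmeiosis" in set(out["category"])
        assert "postmeiosis" not in set(out["category"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            st.composition_compare([], [StageCategory.MITOSIS])

    def test_compare_strata_skips_denovo(self):
        pairs, cats = _toy_scored_pairs()
        rec = st.score_pairs(pairs, cats)
        rec.loc[0, "parent_id"] = None  # make one stratum de-novo-only
        out = compare_strata(rec, cats, by="route")
        assert "XtoA" not in out
        assert "AtoA_intra" in out


class TestPairExpressionTable:
    def test_long_form_rows_per_pair(self, small_universe, small_run):
        cfg, annot, labels, pair_table = small_universe
        _, _, profile, _ = small_run
        routed = st.load_pairs(pair_table, annot)
        table = st.pair_expression_table(routed.head(5), profile)
        # 4 cell types per present gene, parent and child
        assert set(table["cell_type"]) == set(st.CELL_TYPES)
        assert set(table["role"]) <= {"parent", "child"}
        per_pair = table.groupby("child_id").size()
        assert (per_pair <= 8).all() and (per_pair >= 4).all()
        assert (table["pct_expressing"].between(0, 100)).all()


class TestShiftSpectrum:
    def test_all_pairs_one_four(self):
        cats = pd.Series(
            {
                **{f"p{i}": StageCategory.MITOSIS for i in range(6)},
                **{f"c{i}": StageCategory.MEIOSIS_POSTMEIOSIS for i in range(6)},
            }
        )
        cats.index.name = "gene_id"
        pairs = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(6)],
                "parent_id": [f"p{i}" for i in range(6)],
                "branch": [1] * 6,
                "mechanism": ["RNA"] * 6,
                "route": ["XtoA"] * 6,
            }
        )
        spec = st.shift_spectrum(st.score_pairs(pairs, cats))
        assert len(spec) == 1
        assert spec.loc[0, "pct_into_meiosis"] == pytest.approx(100.0)
        assert spec.loc[0, "shift_3"] == 6

    def test_direction_percentages_partition(self, small_universe):
        cfg, annot, labels, pair_table = small_universe
        cats = labels.map(
            lambda a: StageCategory[a] if a != "NOT_EXPRESSED"
            else StageCategory.NOT_EXPRESSED
        )
        routed = st.load_pairs(pair_table, annot)
        spec = st.shift_spectrum(st.score_pairs(routed, cats))
        scored = spec[spec["n_scored"] > 0]
        totals = sum(scored[f"pct_{d}"] for d in DIRECTIONS)
        np.testing.assert_allclose(totals, 100.0, atol=1e-9)
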