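"""The synthetic-data generator: determinism, planting, recovery."""

import numpy as np
import pandas as pd
import pytest

import stagetraffic as st
from stagetraffic.synth import (
    ARCHETYPE_PROGRAMS,
    ARCHETYPE_RANK,
    SynthConfig,
)


class TestConfig:
    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="chrom_props"):
            SynthConfig(chrom_props={"2L": 0.5, "X": 0.2})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_genes_per_archetype=-1)
        with pytest.raises(ValueError):
            SynthConfig(noise_dispersion=-0.1)

    def test_yaml_roundtrip(self):
        cfg = SynthConfig(seed=9, depth_mean=1234.0)
        again = SynthConfig.from_yaml(cfg.to_yaml())
        assert again == cfg

    def test_archetype_programs_maximal_on_named_cells(self):
        named = {
            "MITOSIS": {0}, "MITOSIS_MEIOSIS": {0, 1}, "MEIOSIS": {1, 2},
            "MEIOSIS_POSTMEIOSIS": {2, 3}, "POSTMEIOSIS": {3},
        }
        for arch, cells in named.items():
            prog = np.array(ARCHETYPE_PROGRAMS[arch])
            assert set(np.flatnonzero(prog == prog.max())) == cells
        assert all(v == 0 for v in ARCHETYPE_PROGRAMS["NOT_EXPRESSED"])


class TestGenerateUniverse:
    def test_counts_add_up(self):
        cfg = SynthConfig(n_genes_per_archetype=10, seed=0)
        annot, labels = st.generate_universe(cfg)
        assert len(annot) == 60
        assert labels.value_counts().eq(10).all()

    def test_one_hot_chromosome(self):
        props = {c: 0.0 for c in st.CHROMOSOMES}
        props["X"] = 1.0
        cfg = SynthConfig(n_genes_per_archetype=5, chrom_props=props, seed=0)
        annot, _ = st.generate_universe(cfg)
        assert (annot["chromosome"] == "X").all()

    def test_same_seed_byte_identical(self):
        cfg = SynthConfig(seed=21, n_genes_per_archetype=20)
        a_annot, a_labels = st.generate_universe(cfg)
        b_annot, b_labels = st.generate_universe(cfg)
        assert a_annot.to_csv() == b_annot.to_csv()
        pa, aa, la = st.generate_pairs(a_annot, a_labels, cfg)
        pb, ab, lb = st.generate_pairs(b_annot, b_labels, cfg)
        assert pa.to_csv() == pb.to_csv()
        ca = st.generate_counts(la, cfg)
        cb = st.generate_counts(lb, cfg)
        assert (ca.counts != cb.counts).nnz == 0


class TestGenerateCounts:
    def test_not_expressed_columns_all_zero(self):
        cfg = SynthConfig(seed=4, n_genes_per_archetype=10, cells_per_type=5)
        _, labels = st.generate_universe(cfg)
        data = st.generate_counts(labels, cfg)
        zero_cols = np.asarray(data.counts.sum(axis=0)).ravel() == 0
        planted = (labels == "NOT_EXPRESSED").to_numpy()
        assert (zero_cols[planted]).all()

    def test_noiseless_means_match_program_ranks(self):
        cfg = SynthConfig(
            seed=4, n_genes_per_archetype=5, cells_per_type=200,
            depth_mean=50_000, noise_dispersion=0.0, n_pairs_by_route_mech={},
        )
        _, labels = st.generate_universe(cfg)
        data = st.generate_counts(labels, cfg)
        dense = np.asarray(data.counts.todense(), dtype=float)
        for j, (gid, arch) in enumerate(labels.items()):
            if arch == "NOT_EXPRESSED":
                continue
            means = [
                dense[data.cell_types == ct, j].mean() for ct in st.CELL_TYPES
            ]
            prog = np.array(ARCHETYPE_PROGRAMS[arch])
            assert np.argmax(means) in np.flatnonzero(prog == prog.max())

    def test_zero_cells_rejected(self):
        cfg = SynthConfig(seed=0, cells_per_type=0)
        _, labels = st.generate_universe(cfg)
        with pytest.raises(ValueError):
            st.generate_counts(labels, cfg)


class TestGeneratePairs:
    def test_forced_shift_children_above_rank_one(self):
        cfg = SynthConfig(
            seed=5,
            n_pairs_by_route_mech={("XtoA", "RNA"): 50},
            p_into_meiosis={"default": 1.0},
            parent_archetype_weights={"MITOSIS": 1.0},
        )
        annot, labels = st.generate_universe(cfg)
        pair_table, annot2, labels2 = st.generate_pairs(annot, labels, cfg)
        child_ranks = labels2[pair_table["child_id"]].map(ARCHETYPE_RANK)
        assert (child_ranks >= 2).all()

    def test_no_shift_distribution_centered_at_zero(self):
        cfg = SynthConfig(
            seed=6,
            n_pairs_by_route_mech={("AtoA_inter", "DNA"): 500},
            p_into_meiosis={"default": 0.0},
        )
        annot, labels = st.generate_universe(cfg)
        pair_table, _, labels2 = st.generate_pairs(annot, labels, cfg)
        shifts = (
            labels2[pair_table["child_id"]].map(ARCHETYPE_RANK).to_numpy()
            - labels2[pair_table["parent_id"]].map(ARCHETYPE_RANK).to_numpy()
        )
        se = shifts.std(ddof=1) / np.sqrt(len(shifts))
        assert abs(shifts.mean()) <= max(2 * se, 1e-12)

    def test_routes_consistent_with_chromosomes(self, small_universe):
        cfg, annot, labels, pair_table = small_universe
        routed = st.load_pairs(pair_table, annot)
        chrom = annot.set_index("gene_id")["chromosome"]
        for rec in routed.itertuples(index=False):
            if rec.parent_id is None:
                assert rec.route is None
                continue
            expected = st.derive_route(chrom[rec.parent_id], chrom[rec.child_id])
            assert rec.route == expected
        dup = routed[routed["parent_id"].notna()]
        x_to_a = dup["route"] == "XtoA"
        parent_on_x = dup["parent_id"].map(chrom) == "X"
        child_on_a = dup["child_id"].map(chrom).isin(st.AUTOSOMES)
        assert (x_to_a == (parent_on_x & child_on_a)).all()

    def test_infeasible_stratum_raises(self):
        props = {c: 0.0 for c in st.CHROMOSOMES}
        props["2L"] = 1.0  # no X-linked genes exist
        cfg = SynthConfig(
            seed=0, n_genes_per_archetype=5, chrom_props=props,
            n_pairs_by_route_mech={("XtoA", "RNA"): 5},
        )
        annot, labels = st.generate_universe(cfg)
        with pytest.raises(RuntimeError, match="XtoA"):
            st.generate_pairs(annot, labels, cfg)


class TestRecovery:
    def test_recovery_non_increasing_in_noise(self):
        # aggregate without QC so the gradient reflects classification
        # noise, not cells starved below the detected-gene threshold
        recov = []
        for disp in (0.0, 4.0, 40.0):
            cfg = SynthConfig(
                seed=13, n_genes_per_archetype=60, cells_per_type=40,
                depth_mean=2000.0, noise_dispersion=disp,
                n_pairs_by_route_mech={},
            )
            _, labels = st.generate_universe(cfg)
            data = st.generate_counts(labels, cfg)
            prof = st.aggregate(data)
            cats = st.classify_genes(prof)
            truth = labels[cats.index]
            mask = truth != "NOT_EXPRESSED"
            rate = (
                cats.loc[mask, "category"].map(lambda c: c.name)
                == truth[mask]
            ).mean()
            recov.append(rate)
        assert recov[0] >= recov[1] >= recov[2]
        assert recov[0] >= 0.95
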