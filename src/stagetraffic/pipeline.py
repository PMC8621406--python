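"""End-to-end orchestration: synth or real inputs through every stage.

``run_pipeline`` wires the modules together — generate (or load) counts,
QC-filter, aggregate, classify, chromosomal enrichment, pair shift
scoring and the retrogene traffic test — and writes every intermediate
table plus a manifest recording the seed, a config hash and the record
counts at each step, so a run is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, classify, enrichment, io, pairs, synth, traffic
from .core import StageCategory
from .ingest import aggregate, qc_filter

log = logging.getLogger(__name__)

#: Approximate D. melanogaster chromosome arm lengths (bp), used when no
#: chromosome-length table is supplied.
DEFAULT_CHROM_LENGTHS = pd.Series(
    {
        "2L": 23_513_712,
        "2R": 25_286_936,
        "3L": 28_110_227,
        "3R": 32_079_331,
        "4": 1_348_131,
        "X": 23_542_271,
        "Y": 3_667_352,
    },
    name="bp",
)


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic unless input paths given)."""

    outdir: str = "stagetraffic_out"
    seed: int = 0
    k: int = 7
    theta: float = 0.0
    mode: str = "mean"  # clustering variant: mean log2(CPM+1) or pct
    pooling: str = "meiosis_postmeiosis"
    counts_dir: str | None = None  # MTX directory; None -> synthetic
    annotations: str | None = None
    pairs_table: str | None = None
    chrom_lengths: str | None = None
    synth: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = repr(sorted(dataclasses.asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under config.outdir.

    Returns the manifest dict (also written as manifest.json).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stagetraffic_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": {},
    }

    if config.counts_dir is None:
        scfg = synth.SynthConfig(seed=config.seed, **config.synth)
        annot, labels = synth.generate_universe(scfg)
        pair_table, annot, labels = synth.generate_pairs(annot, labels, scfg)
        data = synth.generate_counts(labels, scfg)
        labels.to_frame().to_csv(outdir / "true_archetypes.tsv", sep="\t")
        manifest["synthetic"] = True
    else:
        data = io.read_counts_mtx(config.counts_dir)
        if config.annotations is None or config.pairs_table is None:
            raise FileNotFoundError(
                "real-data runs need --annotations and --pairs tables"
            )
        annot = io.read_annotations(config.annotations)
        pair_table = io.read_pairs(config.pairs_table)
        manifest["synthetic"] = False
    annot.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pair_table.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    manifest["counts"]["genes_in"] = data.n_genes
    manifest["counts"]["cells_in"] = data.n_cells

    filtered = qc_filter(data)
    dropped_genes = sorted(set(data.gene_ids) - set(filtered.gene_ids))
    manifest["counts"]["genes_after_qc"] = filtered.n_genes
    manifest["counts"]["cells_after_qc"] = filtered.n_cells
    manifest["qc_dropped_genes"] = dropped_genes

    profile = aggregate(filtered)
    io.write_profile(profile, outdir / "profile.tsv")

    categories = classify.classify_genes(
        profile, k=config.k, mode=config.mode, theta=config.theta
    )
    io.write_categories(categories, outdir / "categories.tsv")
    cat_series = categories["category"]
    cat_counts = cat_series.value_counts()
    manifest["counts"]["by_category"] = {
        c.value: int(cat_counts.get(c, 0)) for c in StageCategory
    }
    manifest["counts"]["expressed"] = int(
        (cat_series != StageCategory.NOT_EXPRESSED).sum()
    )

    # genes that passed QC but are absent from the annotation are reported
    chrom_counts = enrichment.count_by_chrom(cat_series, annot)
    chrom_counts.to_csv(outdir / "chrom_category_counts.tsv", sep="\t")
    enrich = enrichment.enrich_all(chrom_counts, pooling=config.pooling)
    enrich.to_csv(outdir / "chrom_enrichment.tsv", sep="\t", index=False)
    ratios = enrichment.ratio_table(chrom_counts)
    ratios.to_csv(outdir / "chrom_ratios.tsv", sep="\t")

    routed = pairs.load_pairs(pair_table, annot)
    records = pairs.score_pairs(routed, cat_series)
    records.to_csv(outdir / "shift_records.tsv", sep="\t", index=False)
    spectrum = pairs.shift_spectrum(records)
    spectrum.to_csv(outdir / "shift_spectrum.tsv", sep="\t", index=False)
    nonoverlap = pairs.nonoverlap_fraction(routed, cat_series, by="branch")
    nonoverlap.to_csv(outdir / "nonoverlap_by_branch.tsv", sep="\t")
    manifest["counts"]["pairs"] = len(records)
    manifest["counts"]["pairs_scored"] = int(records["shift"].notna().sum())

    lengths = (
        DEFAULT_CHROM_LENGTHS
        if config.chrom_lengths is None
        else io.read_chrom_lengths(config.chrom_lengths)
    )
    tt = traffic.traffic_analysis(routed, annot, lengths, mechanism="RNA")
    tt.observed.to_csv(outdir / "traffic_observed.tsv", sep="\t")
    tt.expected.to_csv(outdir / "traffic_expected.tsv", sep="\t", float_format="%.6g")
    tt.summary().to_csv(outdir / "traffic_test.tsv", sep="\t", index=False)
    manifest["traffic"] = {"chi2": tt.chi2, "df": tt.df, "p": tt.p, "N": tt.N}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; bundle written to %s", outdir)
    return manifest
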