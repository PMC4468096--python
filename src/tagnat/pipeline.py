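"""End-to-end pipeline orchestration.

``run_pipeline`` drives one reproducible run: (optionally) simulate the
study, build the reference tag DB, clean and map every library, assemble
the stranded TPM matrix, profile antisense transcription, call DEGs and
NATs, and run term enrichment on the significant set.  Every stage's
summary lands in the :class:`RunReport`; a manifest echoes every parameter
and seed so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import diffexpr, quantify, refdb, simulate, tags
from .enrich import enrich as run_enrichment, enrichment_frame, read_term_map

logger = logging.getLogger(__name__)

_DEFAULT_ADAPTER = simulate.DEFAULT_ADAPTER


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the protocol's standard defaults."""

    outdir: str = "tagnat_run"
    seed: int = 0
    # simulation (used when no external reads are given)
    simulate: bool = True
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (300, 3000)
    catg_gene_fraction: float = 0.979
    n_de: int = 40
    n_de_nat: int = 8
    effect_log2: float = 2.0
    nat_fraction: float = 0.33
    nat_corr: float = 0.55
    depth: int = 5_000_000
    error_rate: float = 0.0
    n_per_group: int = 3
    jitter_sigma: float = 0.2
    adapter: str = _DEFAULT_ADAPTER
    # external inputs (alternative to simulation)
    genome_fasta: Optional[str] = None
    annotation_bed: Optional[str] = None
    fastq: dict = field(default_factory=dict)  # sample_id -> path
    design: dict = field(default_factory=dict)  # sample_id -> group (S|F)
    term_map: Optional[str] = None
    # stage parameters
    min_tag_len: int = refdb.TAG_LEN
    drop_singletons: bool = True
    max_mismatch: int = 1
    pseudo_k: float = diffexpr.DEFAULT_K
    min_abs_m: float = 1.0
    min_prob: float = 0.8
    min_tpm_low: float = 1.0
    alpha: float = 0.05
    write_outputs: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.min_prob <= 1.0:
            raise ValueError(f"min_prob must be in [0,1], got {self.min_prob}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.pseudo_k <= 0:
            raise ValueError("pseudo_k must be > 0")
        if not self.simulate:
            if not (self.genome_fasta and self.annotation_bed and self.fastq and self.design):
                raise ValueError(
                    "without simulation, genome_fasta, annotation_bed, fastq and design "
                    "are required"
                )


@dataclass
class RunReport:
    config: RunConfig
    refdb_stats: dict
    library_summaries: pd.DataFrame  # per-sample clean-tag totals
    mapping_summaries: pd.DataFrame  # sense + antisense rows per sample
    nat_profile: pd.DataFrame
    de_records: pd.DataFrame
    significant_counts: dict
    enrichment: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.outdir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # --- inputs ------------------------------------------------------------
    if config.simulate:
        genome = simulate.generate_genome(
            config.n_genes, config.gene_length_range, config.catg_gene_fraction, config.seed
        )
        truth = simulate.assign_expression(
            genome,
            n_de=config.n_de,
            effect_log2=config.effect_log2,
            nat_fraction=config.nat_fraction,
            nat_corr=config.nat_corr,
            seed=config.seed + 1,
            n_de_nat=config.n_de_nat,
            pseudo_k=config.pseudo_k,
        )
        libs = simulate.simulate_experiment(
            genome,
            truth,
            depth=config.depth,
            error_rate=config.error_rate,
            seed=config.seed + 2,
            n_per_group=config.n_per_group,
            jitter_sigma=config.jitter_sigma,
            adapter=config.adapter,
        )
        design = {lib.sample_id: lib.group for lib in libs}
        term_df = simulate.simulate_term_map(genome, seed=config.seed + 100)
        if config.write_outputs:
            simulate.write_genome_fasta(genome, out / "genome.fa")
            simulate.write_annotation_bed(genome, out / "genes.bed")
            simulate.write_truth(truth, out / "truth.tsv")
            term_df.to_csv(out / "term_map.tsv", sep="\t", index=False)
        raw_inputs = libs
    else:
        genome = simulate.read_genome(config.genome_fasta, config.annotation_bed)
        truth = None
        design = dict(config.design)
        term_df = read_term_map(config.term_map) if config.term_map else None
        raw_inputs = list(config.fastq.items())  # (sample_id, path)

    # --- reference DB ------------------------------------------------------
    db = refdb.build_reference_db(genome.genes)
    gene_ids = [g.gene_id for g in genome.genes]
    if config.write_outputs:
        refdb.write_db(db, str(out / "refdb.tsv.gz"), str(out / "refdb_stats.json"))

    # --- clean + map -------------------------------------------------------
    cleans: list[tags.CleanTagLibrary] = []
    mappings: list[tags.MappingResult] = []
    for item in raw_inputs:
        if config.simulate:
            lib = tags.clean_reads(
                item,
                adapter=config.adapter,
                min_tag_len=config.min_tag_len,
                drop_singletons=config.drop_singletons,
            )
        else:
            sample_id, path = item
            lib = tags.clean_reads(
                path,
                adapter=config.adapter,
                min_tag_len=config.min_tag_len,
                drop_singletons=config.drop_singletons,
                sample_id=sample_id,
            )
        cleans.append(lib)
        mappings.append(tags.map_tags(lib, db, max_mismatch=config.max_mismatch))
        logger.info("%s: %d clean tags, %d distinct", lib.sample_id, lib.total_clean, lib.distinct_clean)

    lib_rows = [
        {
            "sample_id": c.sample_id,
            "group": design[c.sample_id],
            "clean_total": c.total_clean,
            "clean_distinct": c.distinct_clean,
            **{f"dropped_{k}": v for k, v in c.dropped.items()},
        }
        for c in cleans
    ]
    map_rows = []
    for m, c in zip(mappings, cleans):
        for layer in ("sense", "antisense"):
            map_rows.append(quantify.summarize_library(m, c, len(gene_ids), layer=layer))

    # --- matrix + NAT profile ----------------------------------------------
    totals = {c.sample_id: c.total_clean for c in cleans}
    matrix = quantify.build_matrix(mappings, totals, gene_ids)
    profile = quantify.nat_profile(matrix, mappings, len(gene_ids))
    if config.write_outputs:
        for layer in ("sense", "antisense"):
            matrix.layer(layer, tpm=False).to_csv(out / f"counts_{layer}.tsv", sep="\t")
            matrix.layer(layer, tpm=True).to_csv(out / f"tpm_{layer}.tsv", sep="\t")
        profile.per_sample.to_csv(out / "nat_profile.tsv", sep="\t", index=False)

    # --- differential expression -------------------------------------------
    records = diffexpr.run_differential(matrix, design, k=config.pseudo_k)
    sig = diffexpr.call_significant(
        records,
        min_abs_m=config.min_abs_m,
        min_prob=config.min_prob,
        min_tpm_low=config.min_tpm_low,
    )
    sig_counts = {
        "degs_up": len(sig.degs_up),
        "degs_down": len(sig.degs_down),
        "nats_up": len(sig.nats_up),
        "nats_down": len(sig.nats_down),
        "total": sig.total,
    }
    de_frame = diffexpr.records_to_frame(records)
    if config.write_outputs:
        de_frame[de_frame["significant"]].to_csv(out / "significant.tsv", sep="\t", index=False)
        de_frame.to_csv(out / "de_records.tsv", sep="\t", index=False)
        (out / "significant_counts.json").write_text(json.dumps(sig_counts, indent=1))

    # --- enrichment ---------------------------------------------------------
    sig_genes = {
        r.transcript_id
        for lst in (sig.degs_up, sig.degs_down, sig.nats_up, sig.nats_down)
        for r in lst
    }
    if term_df is not None and sig_genes:
        terms = run_enrichment(sig_genes, set(gene_ids), term_df, alpha=config.alpha)
        enr_frame = enrichment_frame(terms)
    else:
        enr_frame = pd.DataFrame()
    if config.write_outputs and not enr_frame.empty:
        enr_frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "refdb": db.stats.to_dict(),
        "samples": list(totals),
    }
    if config.write_outputs:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return RunReport(
        config=config,
        refdb_stats=db.stats.to_dict(),
        library_summaries=pd.DataFrame(lib_rows),
        mapping_summaries=pd.DataFrame(map_rows),
        nat_profile=profile.per_sample,
        de_records=de_frame,
        significant_counts=sig_counts,
        enrichment=enr_frame,
        manifest=manifest,
    )
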