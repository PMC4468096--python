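"""Synthetic DGE study generator.

Emulates a tag-based digital gene expression experiment on skin from two
sheep groups differing in wool fiber diameter: a super-fine group ``S`` and
a fine group ``F``, three biological replicates each.  The generator
produces

* a genome with annotated genes, ~98% of which carry at least one usable
  NlaIII site (``CATG`` with 17 downstream bases);
* an expression truth table with a log-normal abundance distribution, a
  planted set of differentially expressed genes, and antisense
  transcription on ~33% of genes whose level is rank-correlated with the
  sense level (target Spearman ~0.55) and totals ~1/10 of the sense tag
  mass;
* per-sample raw 35-base reads: the 21-base tag (CATG + 17 transcribed
  bases) followed by a constant 3' adapter, with optional per-base
  substitution errors.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .refdb import TAG_LEN, extract_tags, find_tag_sites, reverse_complement

logger = logging.getLogger(__name__)

READ_LEN = 35
#: Constant 3' adapter ligated after the MmeI cut; 14 bases so tag+adapter = 35.
DEFAULT_ADAPTER = "TCGTATGCCGTCTT"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"
    sequence: str  # gene-forward orientation

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1}"
            )


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    genes: list[GeneModel]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene identifiers are not unique")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if not (1 <= g.start <= g.end <= len(self.chromosomes[g.chrom])):
                raise ValueError(f"{g.gene_id}: interval outside chromosome bounds")


@dataclass
class ExpressionTruth:
    """Planted per-gene, per-group expected abundances (tags per million).

    ``table`` columns: gene_id, sense_S, sense_F, antisense_S, antisense_F,
    de_flag, de_direction, nat_flag, nat_de_flag, nat_de_direction.
    """

    table: pd.DataFrame
    effect_log2: float
    pseudo_k: float

    def de_genes(self) -> list[str]:
        return list(self.table.loc[self.table["de_flag"], "gene_id"])

    def nat_de_genes(self) -> list[str]:
        return list(self.table.loc[self.table["nat_de_flag"], "gene_id"])


@dataclass
class RawLibrary:
    sample_id: str
    group: str
    reads: list[str]
    seed: int


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _scrub_catg(seq: str, rng: np.random.Generator) -> str:
    """Remove every CATG occurrence by resampling its G (repeat to fixpoint)."""
    s = list(seq)
    while True:
        i = "".join(s).find("CATG")
        if i == -1:
            return "".join(s)
        s[i + 3] = rng.choice(np.array(list("ACT")))


def generate_genome(
    n_genes: int,
    gene_length_range: tuple[int, int] = (300, 3000),
    catg_gene_fraction: float = 0.979,
    seed: int = 0,
    spacer: int = 50,
) -> SyntheticGenome:
    """Random genome of ``n_genes`` genes laid head-to-tail on one chromosome.

    Each gene independently carries a usable CATG site with probability
    ``catg_gene_fraction`` (sites are planted or scrubbed as needed); minus-
    strand genes are stored reverse-complemented on the chromosome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo < 25 or hi < lo:
        raise ValueError(f"invalid gene_length_range {gene_length_range}")
    if not 0.0 <= catg_gene_fraction <= 1.0:
        raise ValueError(f"catg_gene_fraction must be in [0,1], got {catg_gene_fraction}")
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based running position on chr1
    width = len(str(n_genes))
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_dna(rng, length)
        bearing = rng.random() < catg_gene_fraction
        if bearing:
            if not find_tag_sites(seq):
                at = int(rng.integers(0, length - TAG_LEN + 1))
                # offset bound guarantees 17 downstream bases, so the planted
                # site is always usable
                seq = seq[:at] + "CATG" + seq[at + 4 :]
        else:
            seq = _scrub_catg(seq, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        gap = _random_dna(rng, spacer)
        pieces.append(gap)
        pos += spacer
        start = pos + 1
        pieces.append(seq if strand == "+" else reverse_complement(seq))
        pos += length
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:0{width}d}",
                chrom="chr1",
                start=start,
                end=pos,
                strand=strand,
                sequence=seq,
            )
        )
    return SyntheticGenome(chromosomes={"chr1": "".join(pieces)}, genes=genes)


def _spearman_to_pearson(rs: float) -> float:
    """Gaussian-copula Pearson rho giving target Spearman rank correlation."""
    return 2.0 * math.sin(math.pi * rs / 6.0)


def assign_expression(
    genome: SyntheticGenome,
    n_de: int = 40,
    effect_log2: float = 2.0,
    nat_fraction: float = 0.33,
    nat_corr: float = 0.55,
    seed: int = 0,
    n_de_nat: int = 0,
    sense_antisense_ratio: float = 10.0,
    log_sd: float = 1.5,
    pseudo_k: float = 0.5,
    de_abundance_quantile: float = 0.6,
) -> ExpressionTruth:
    """Plant per-group expected abundances with DE genes and correlated NATs.

    Sense abundances are log-normal across genes.  ``nat_fraction`` of genes
    get a nonzero antisense level generated from a Gaussian copula so that
    the log-scale rank correlation with the sense level is ~``nat_corr``,
    scaled so total antisense mass is 1/``sense_antisense_ratio`` of sense.
    ``n_de`` genes (``n_de_nat`` antisense layers) are shifted in group S so
    that |log2((S+k)/(F+k))| equals ``effect_log2`` exactly at ``pseudo_k``.
    """
    n_genes = len(genome.genes)
    if n_de > n_genes:
        raise ValueError(f"n_de={n_de} exceeds number of genes {n_genes}")
    if not 0.0 <= nat_corr <= 1.0:
        raise ValueError("nat_corr must be in [0,1]")
    rng = np.random.default_rng(seed)

    z_sense = rng.standard_normal(n_genes)
    sense = np.exp(log_sd * z_sense)

    rho = _spearman_to_pearson(nat_corr)
    z_anti = rho * z_sense + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(
        n_genes
    )
    nat_flag = rng.random(n_genes) < nat_fraction
    anti = np.where(nat_flag, np.exp(log_sd * z_anti), 0.0)
    if anti.sum() > 0:
        anti *= sense.sum() / sense_antisense_ratio / anti.sum()

    # express everything in expected tags per million of the F library
    scale = 1e6 / (sense.sum() + anti.sum())
    sense_f = sense * scale
    anti_f = anti * scale
    sense_s = sense_f.copy()
    anti_s = anti_f.copy()

    k, e = pseudo_k, effect_log2
    fold = 2.0**e
    de_flag = np.zeros(n_genes, dtype=bool)
    de_dir = np.array(["none"] * n_genes, dtype=object)
    # plant DE on genes expressed above the noise floor: a nonparametric
    # caller that pools noise pairs across all genes cannot resolve fold
    # changes on genes whose absolute difference D is below the bulk of the
    # noise-D distribution, so detectable DE lives in the upper abundance
    # range (de_abundance_quantile of the sense distribution)
    floor = max(
        float(np.quantile(sense_f, de_abundance_quantile)),
        2.0 * k * (fold - 1.0),
        5.0,
    )
    eligible = np.flatnonzero(sense_f >= floor)
    if n_de > len(eligible):
        raise ValueError(
            f"n_de={n_de} exceeds the {len(eligible)} genes abundant enough to carry "
            f"a {effect_log2}-log2 shift"
        )
    chosen = rng.choice(eligible, size=n_de, replace=False)
    for j, g in enumerate(chosen):
        de_flag[g] = True
        if j % 2 == 0:
            sense_s[g] = fold * sense_f[g] + (fold - 1.0) * k
            de_dir[g] = "up_in_S"
        else:
            sense_s[g] = (sense_f[g] + k) / fold - k
            de_dir[g] = "down_in_S"

    nat_de_flag = np.zeros(n_genes, dtype=bool)
    nat_de_dir = np.array(["none"] * n_genes, dtype=object)
    nat_levels = anti_f[nat_flag]
    nat_floor = max(
        float(np.quantile(nat_levels, de_abundance_quantile)) if nat_levels.size else 0.0,
        2.0 * k * (fold - 1.0),
        5.0,
    )
    nat_eligible = np.flatnonzero(nat_flag & (anti_f >= nat_floor))
    if n_de_nat > len(nat_eligible):
        raise ValueError(
            f"n_de_nat={n_de_nat} exceeds the {len(nat_eligible)} eligible NAT genes"
        )
    chosen_nat = rng.choice(nat_eligible, size=n_de_nat, replace=False)
    for j, g in enumerate(chosen_nat):
        nat_de_flag[g] = True
        if j % 2 == 0:
            anti_s[g] = fold * anti_f[g] + (fold - 1.0) * k
            nat_de_dir[g] = "up_in_S"
        else:
            anti_s[g] = (anti_f[g] + k) / fold - k
            nat_de_dir[g] = "down_in_S"

    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genome.genes],
            "sense_S": sense_s,
            "sense_F": sense_f,
            "antisense_S": anti_s,
            "antisense_F": anti_f,
            "de_flag": de_flag,
            "de_direction": de_dir,
            "nat_flag": nat_flag,
            "nat_de_flag": nat_de_flag,
            "nat_de_direction": nat_de_dir,
        }
    )
    return ExpressionTruth(table=table, effect_log2=effect_log2, pseudo_k=pseudo_k)


def _usable_tags(gene: GeneModel, strand_relation: str) -> list[str]:
    seq = gene.sequence if strand_relation == "sense" else reverse_complement(gene.sequence)
    return [tag for tag, _ in extract_tags(seq) if "N" not in tag]


def simulate_library(
    genome: SyntheticGenome,
    truth: ExpressionTruth,
    sample_id: str,
    group: str,
    depth: int = 5_000_000,
    error_rate: float = 0.0,
    seed: int = 0,
    jitter_sigma: float = 0.2,
    adapter: str = DEFAULT_ADAPTER,
    site_weights: Callable[[GeneModel, str, list[str]], np.ndarray] | None = None,
) -> RawLibrary:
    """Draw ``depth`` 35-base reads for one replicate.

    Expected tag counts per (gene, strand) follow the truth's group means
    with per-replicate log-normal jitter (``jitter_sigma``), drawn
    multinomially.  Each read is a uniformly chosen CATG+17 tag of the gene
    on the transcribed strand, the adapter, and random filler to 35 bases.
    Genes drawn for a strand with no usable CATG site contribute zero tags
    (logged).  ``site_weights`` optionally biases the site choice.
    """
    if group not in ("S", "F"):
        raise ValueError("group must be 'S' or 'F'")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    t = truth.table
    weights = np.concatenate([t[f"sense_{group}"], t[f"antisense_{group}"]]).astype(float)
    weights = weights * np.exp(rng.normal(0.0, jitter_sigma, size=weights.size))
    total = weights.sum()
    reads: list[str] = []
    if depth > 0 and total > 0:
        counts = rng.multinomial(depth, weights / total)
        n = len(genome.genes)
        for idx in np.flatnonzero(counts):
            gene = genome.genes[idx % n]
            strand_relation = "sense" if idx < n else "antisense"
            tags = _usable_tags(gene, strand_relation)
            if not tags:
                logger.warning(
                    "%s: gene %s has no usable CATG site on its %s strand; "
                    "%d tags dropped",
                    sample_id,
                    gene.gene_id,
                    strand_relation,
                    counts[idx],
                )
                continue
            if site_weights is not None:
                p = np.asarray(site_weights(gene, strand_relation, tags), dtype=float)
                picks = rng.choice(len(tags), size=counts[idx], p=p / p.sum())
            else:
                picks = rng.integers(0, len(tags), size=counts[idx])
            fill_len = READ_LEN - TAG_LEN - len(adapter)
            for s in picks:
                read = tags[s] + adapter
                if fill_len > 0:
                    read += _random_dna(rng, fill_len)
                reads.append(read[:READ_LEN])
    if error_rate > 0.0 and reads:
        reads = _inject_errors(reads, error_rate, rng)
    return RawLibrary(sample_id=sample_id, group=group, reads=reads, seed=seed)


def _inject_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    out = []
    for read in reads:
        hits = np.flatnonzero(rng.random(len(read)) < error_rate)
        if hits.size == 0:
            out.append(read)
            continue
        chars = list(read)
        for i in hits:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[rng.integers(0, 3)]
        out.append("".join(chars))
    return out


def simulate_experiment(
    genome: SyntheticGenome,
    truth: ExpressionTruth,
    depth: int = 5_000_000,
    error_rate: float = 0.0,
    seed: int = 0,
    n_per_group: int = 3,
    jitter_sigma: float = 0.2,
    adapter: str = DEFAULT_ADAPTER,
) -> list[RawLibrary]:
    """Two groups of ``n_per_group`` replicates; sample i uses seed ``seed+i``."""
    libs = []
    i = 0
    for group in ("S", "F"):
        for r in range(1, n_per_group + 1):
            libs.append(
                simulate_library(
                    genome,
                    truth,
                    sample_id=f"{group}{r}",
                    group=group,
                    depth=depth,
                    error_rate=error_rate,
                    seed=seed + i,
                    jitter_sigma=jitter_sigma,
                    adapter=adapter,
                )
            )
            i += 1
    return libs


def simulate_term_map(
    genome: SyntheticGenome,
    n_terms: int = 40,
    annotated_fraction: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Flat gene→term annotation: each annotated gene gets 1–4 random terms."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genome.genes:
        if rng.random() >= annotated_fraction:
            continue
        k = int(rng.integers(1, 5))
        for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
            rows.append(
                (gene.gene_id, f"T{t + 1:04d}", f"synthetic term {t + 1}", "synthetic")
            )
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_label", "namespace"])


# ---------------------------------------------------------------------------
# file I/O


def write_genome_fasta(genome: SyntheticGenome, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_annotation_bed(genome: SyntheticGenome, path: str) -> None:
    """6-column BED (0-based half-open): chrom, start, end, gene_id, score, strand."""
    with open(path, "w") as fh:
        for g in genome.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genome(fasta_path: str, bed_path: str) -> SyntheticGenome:
    """Reconstruct the genome object from FASTA + BED6 annotation."""
    from Bio import SeqIO

    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    genes = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end, gene_id, _score, strand = line.rstrip("\n").split("\t")[:6]
            start, end = int(start0) + 1, int(end)
            seg = chroms[chrom][start - 1 : end]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=seg if strand == "+" else reverse_complement(seg),
                )
            )
    return SyntheticGenome(chromosomes=chroms, genes=genes)


def write_truth(truth: ExpressionTruth, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def write_fastq(lib: RawLibrary, path: str, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(lib.reads):
            fh.write(f"@{lib.sample_id}_{i}\n{read}\n+\n{quality_char * len(read)}\n")
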