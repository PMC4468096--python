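"""Reference tag database for NlaIII-anchored expression tags.

Each expression tag is the 4-base NlaIII recognition site ``CATG`` plus the
17 bases immediately downstream on the transcribed strand (21 bases total,
the fragment released by MmeI).  The reference database enumerates every
such tag on both strands of every annotated gene, so that observed tags can
be assigned to a gene and a strand ("sense" when the tag lies on the gene's
own strand, "antisense" when it lies on the opposite strand and therefore
evidences a natural antisense transcript).

A tag string that maps to more than one (gene, strand) pair is *ambiguous*
and is excluded from expression counting downstream.  A tag occurring at
several positions of the same gene and strand stays unambiguous; its counts
are later summed into that gene.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ANCHOR = "CATG"
TAG_TAIL = 17
TAG_LEN = len(ANCHOR) + TAG_TAIL  # 21

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_tag_sites(seq: str) -> list[int]:
    """0-based offsets of every CATG occurrence with >= 17 bases downstream.

    Overlapping occurrences are all reported. Windows containing N are kept
    here; callers decide whether to skip them.
    """
    sites = []
    start = 0
    limit = len(seq) - TAG_LEN
    while True:
        i = seq.find(ANCHOR, start)
        if i == -1 or i > limit:
            break
        sites.append(i)
        start = i + 1
    return sites


def extract_tags(seq: str) -> list[tuple[str, int]]:
    """All (21-base tag, offset) pairs from one strand of a sequence."""
    return [(seq[i : i + TAG_LEN], i) for i in find_tag_sites(seq)]


@dataclass(frozen=True)
class ReferenceTag:
    """One (tag, gene, strand) assignment.

    ``site_offsets`` are 0-based CATG positions within the scanned strand
    (the gene-forward sequence for sense tags, its reverse complement for
    antisense tags); one assignment may cover several positions.
    """

    tag: str
    gene_id: str
    strand_relation: str  # "sense" | "antisense"
    site_offsets: tuple[int, ...]


@dataclass
class RefDbStats:
    n_genes_total: int = 0
    n_genes_with_catg: int = 0
    n_tags_total: int = 0
    n_tags_unambiguous: int = 0
    n_windows_skipped_n: int = 0

    @property
    def pct_genes_with_catg(self) -> float:
        if self.n_genes_total == 0:
            return 0.0
        return round(100.0 * self.n_genes_with_catg / self.n_genes_total, 2)

    @property
    def pct_tags_unambiguous(self) -> float:
        if self.n_tags_total == 0:
            return 0.0
        return round(100.0 * self.n_tags_unambiguous / self.n_tags_total, 2)

    def to_dict(self) -> dict:
        return {
            "n_genes_total": self.n_genes_total,
            "n_genes_with_catg": self.n_genes_with_catg,
            "pct_genes_with_catg": self.pct_genes_with_catg,
            "n_tags_total": self.n_tags_total,
            "n_tags_unambiguous": self.n_tags_unambiguous,
            "pct_tags_unambiguous": self.pct_tags_unambiguous,
            "n_windows_skipped_n": self.n_windows_skipped_n,
        }


@dataclass
class ReferenceTagDB:
    """tag string -> list of (gene, strand) assignments, plus summary stats."""

    entries: dict[str, list[ReferenceTag]] = field(default_factory=dict)
    stats: RefDbStats = field(default_factory=RefDbStats)

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.entries.get(tag, ())) > 1

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for refs in self.entries.values():
            for r in refs:
                seen.setdefault(r.gene_id, None)
        return list(seen)


def build_reference_db(genes: Sequence) -> ReferenceTagDB:
    """Enumerate CATG+17 tags on both strands of every gene.

    ``genes`` are objects with ``gene_id`` and ``sequence`` attributes
    (gene-forward orientation, uppercase A/C/G/T/N).  Tags whose 21-base
    window contains N are skipped and counted in the stats.
    """
    entries: dict[str, list[ReferenceTag]] = {}
    stats = RefDbStats(n_genes_total=len(genes))
    for gene in genes:
        seq = gene.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"gene {gene.gene_id}: sequence contains non-ACGTN characters {sorted(bad)}"
            )
        gene_has_site = False
        for strand_relation, strand_seq in (
            ("sense", seq),
            ("antisense", reverse_complement(seq)),
        ):
            per_tag: dict[str, list[int]] = {}
            for tag, offset in extract_tags(strand_seq):
                if "N" in tag:
                    stats.n_windows_skipped_n += 1
                    continue
                per_tag.setdefault(tag, []).append(offset)
                if strand_relation == "sense":
                    gene_has_site = True
            for tag, offsets in per_tag.items():
                entries.setdefault(tag, []).append(
                    ReferenceTag(tag, gene.gene_id, strand_relation, tuple(offsets))
                )
        if gene_has_site:
            stats.n_genes_with_catg += 1
    stats.n_tags_total = len(entries)
    stats.n_tags_unambiguous = sum(1 for refs in entries.values() if len(refs) == 1)
    db = ReferenceTagDB(entries=entries, stats=stats)
    return db


def db_stats(db: ReferenceTagDB) -> RefDbStats:
    return db.stats


def percentage(part: int, whole: int) -> float:
    """``100 * part / whole`` rounded to 2 decimals; 0.00 when whole is 0."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, 2)


def write_db(db: ReferenceTagDB, tsv_path: str, stats_path: str | None = None) -> None:
    """Write the DB as (gzip) TSV: tag, gene_id, strand_relation, offsets, ambiguous."""
    opener = gzip.open if str(tsv_path).endswith(".gz") else open
    with opener(tsv_path, "wt") as fh:
        fh.write("tag\tgene_id\tstrand_relation\tsite_offsets\tambiguous\n")
        for tag in sorted(db.entries):
            amb = int(len(db.entries[tag]) > 1)
            for ref in db.entries[tag]:
                offs = ",".join(map(str, ref.site_offsets))
                fh.write(f"{tag}\t{ref.gene_id}\t{ref.strand_relation}\t{offs}\t{amb}\n")
    if stats_path is not None:
        with open(stats_path, "w") as fh:
            json.dump(db.stats.to_dict(), fh, indent=1)


def read_db(tsv_path: str) -> ReferenceTagDB:
    opener = gzip.open if str(tsv_path).endswith(".gz") else open
    entries: dict[str, list[ReferenceTag]] = {}
    genes_seen: set[str] = set()
    with opener(tsv_path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("tag\t"):
            raise ValueError(f"{tsv_path}: not a reference tag DB file")
        for line in fh:
            tag, gene_id, strand_relation, offs, _amb = line.rstrip("\n").split("\t")
            offsets = tuple(int(x) for x in offs.split(",")) if offs else ()
            entries.setdefault(tag, []).append(
                ReferenceTag(tag, gene_id, strand_relation, offsets)
            )
            genes_seen.add(gene_id)
    stats = RefDbStats(
        n_genes_total=len(genes_seen),
        n_genes_with_catg=len(genes_seen),
        n_tags_total=len(entries),
        n_tags_unambiguous=sum(1 for refs in entries.values() if len(refs) == 1),
    )
    return ReferenceTagDB(entries=entries, stats=stats)
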