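"""Raw-read cleaning, library saturation, and strand-aware tag mapping.

Cleaning turns 35-base raw reads into a counted library of 21-base tags:
the 3' adapter is located and trimmed, reads whose insert is shorter than
21 bases (or empty) are dropped, and — after counting — singleton tags
(observed exactly once in the library) are discarded as likely sequencing
artifacts.

Mapping assigns each distinct clean tag to a gene and strand against the
reference tag database, allowing at most one mismatch.  An exact hit to a
single (gene, strand) wins outright; an exact hit shared by several
(gene, strand) pairs is discarded as ambiguous; otherwise the Hamming-1
neighborhood is searched among *unambiguous* reference tags only, and the
tag is assigned only when every neighbor hit agrees on one (gene, strand).
Counts landing on several positions of the same gene and strand are summed
into that gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .refdb import TAG_LEN, ReferenceTagDB
from .simulate import RawLibrary


@dataclass
class CleanTagLibrary:
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(
        default_factory=lambda: {"empty": 0, "too_short": 0, "singleton": 0, "low_quality": 0}
    )

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)


@dataclass
class MappingResult:
    sample_id: str
    sense_counts: dict[str, int] = field(default_factory=dict)  # gene -> tags
    antisense_counts: dict[str, int] = field(default_factory=dict)
    # category totals as (total tags, distinct tag species)
    unique_sense: tuple[int, int] = (0, 0)
    unique_antisense: tuple[int, int] = (0, 0)
    ambiguous_discarded: tuple[int, int] = (0, 0)
    unknown: tuple[int, int] = (0, 0)

    @property
    def n_genes_sense_detected(self) -> int:
        return sum(1 for v in self.sense_counts.values() if v > 0)

    @property
    def n_genes_antisense_detected(self) -> int:
        return sum(1 for v in self.antisense_counts.values() if v > 0)

    @property
    def total_assigned(self) -> int:
        return (
            self.unique_sense[0]
            + self.unique_antisense[0]
            + self.ambiguous_discarded[0]
            + self.unknown[0]
        )


def _iter_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (sequence, quality) from a phred-33 FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    idx = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                _title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {idx} in {path}: {exc}"
                ) from exc
            yield seq.upper(), qual
            idx += 1


def _trim_adapter(read: str, adapter: str) -> str:
    """Insert before the adapter; partial adapter prefixes at the 3' end count."""
    i = read.find(adapter)
    if i != -1:
        return read[:i]
    for k in range(min(len(adapter), len(read)) - 1, 0, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return read


def clean_reads(
    raw,
    adapter: str,
    min_tag_len: int = TAG_LEN,
    drop_singletons: bool = True,
    min_mean_quality: float | None = None,
    sample_id: str | None = None,
) -> CleanTagLibrary:
    """Clean raw reads into a counted tag library.

    ``raw`` may be a :class:`~tagnat.simulate.RawLibrary`, an iterable of
    read strings, or a FASTQ path.  ``min_mean_quality`` (phred scale, off
    by default) drops reads below a mean base quality; it only applies to
    FASTQ input, where qualities exist.
    """
    if isinstance(raw, RawLibrary):
        sample_id = sample_id or raw.sample_id
        records: Iterable[tuple[str, str | None]] = ((r, None) for r in raw.reads)
    elif isinstance(raw, (str, Path)):
        sample_id = sample_id or Path(raw).stem.split(".")[0]
        records = _iter_fastq(str(raw))
    else:
        sample_id = sample_id or "sample"
        records = ((r, None) for r in raw)

    lib = CleanTagLibrary(sample_id=sample_id)
    counts: Counter[str] = Counter()
    for read, qual in records:
        if min_mean_quality is not None and qual is not None:
            mean_q = sum(ord(c) - 33 for c in qual) / max(len(qual), 1)
            if mean_q < min_mean_quality:
                lib.dropped["low_quality"] += 1
                continue
        insert = _trim_adapter(read, adapter)
        if len(insert) == 0:
            lib.dropped["empty"] += 1
        elif len(insert) < min_tag_len:
            lib.dropped["too_short"] += 1
        else:
            counts[insert[:min_tag_len]] += 1
    if drop_singletons:
        singles = [t for t, c in counts.items() if c == 1]
        for t in singles:
            del counts[t]
        lib.dropped["singleton"] = len(singles)
    lib.counts = dict(counts)
    return lib


def saturation_curve(
    lib: CleanTagLibrary, n_points: int = 11, seed: int = 0
) -> list[tuple[int, int]]:
    """Distinct tags detected vs. sampling depth (without replacement).

    Depths are ``n_points`` evenly spaced fractions of ``total_clean``; the
    draws are nested (one random permutation of the tag multiset), so the
    curve is non-decreasing and ends at ``distinct_clean``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    tags = list(lib.counts)
    cnt = np.fromiter((lib.counts[t] for t in tags), dtype=np.int64, count=len(tags))
    total = int(cnt.sum())
    expanded = np.repeat(np.arange(len(tags)), cnt)
    rng.shuffle(expanded)
    # position of each tag's first occurrence in the permuted stream
    _, first_idx = np.unique(expanded, return_index=True)
    first_idx.sort()
    curve = []
    for f in np.linspace(0.0, 1.0, n_points):
        m = int(round(f * total))
        curve.append((m, int(np.searchsorted(first_idx, m, side="left"))))
    return curve


def _neighbors(tag: str) -> Iterator[str]:
    """All strings at Hamming distance exactly 1 (same length, ACGT alphabet)."""
    for i, c in enumerate(tag):
        for b in "ACGT":
            if b != c:
                yield tag[:i] + b + tag[i + 1 :]


def map_tags(
    lib: CleanTagLibrary, db: ReferenceTagDB, max_mismatch: int = 1
) -> MappingResult:
    """Assign clean tags to genes/strands; see module docstring for the rules."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    res = MappingResult(sample_id=lib.sample_id)
    totals = {k: [0, 0] for k in ("unique_sense", "unique_antisense", "ambiguous", "unknown")}

    for tag, count in lib.counts.items():
        if len(tag) != TAG_LEN:
            raise ValueError(
                f"tag length {len(tag)} != reference tag length {TAG_LEN}: {tag!r}"
            )
        refs = db.entries.get(tag)
        if refs is not None:
            if len(refs) == 1:
                assignment = (refs[0].gene_id, refs[0].strand_relation)
            else:
                assignment = "ambiguous"
        elif max_mismatch >= 1:
            hits = set()
            for nb in _neighbors(tag):
                nrefs = db.entries.get(nb)
                if nrefs is not None and len(nrefs) == 1:  # unambiguous refs only
                    hits.add((nrefs[0].gene_id, nrefs[0].strand_relation))
            if len(hits) == 1:
                assignment = next(iter(hits))
            elif hits:
                assignment = "ambiguous"
            else:
                assignment = "unknown"
        else:
            assignment = "unknown"

        if assignment == "ambiguous":
            totals["ambiguous"][0] += count
            totals["ambiguous"][1] += 1
        elif assignment == "unknown":
            totals["unknown"][0] += count
            totals["unknown"][1] += 1
        else:
            gene_id, strand_relation = assignment
            if strand_relation == "sense":
                res.sense_counts[gene_id] = res.sense_counts.get(gene_id, 0) + count
                totals["unique_sense"][0] += count
                totals["unique_sense"][1] += 1
            else:
                res.antisense_counts[gene_id] = res.antisense_counts.get(gene_id, 0) + count
                totals["unique_antisense"][0] += count
                totals["unique_antisense"][1] += 1

    res.unique_sense = tuple(totals["unique_sense"])
    res.unique_antisense = tuple(totals["unique_antisense"])
    res.ambiguous_discarded = tuple(totals["ambiguous"])
    res.unknown = tuple(totals["unknown"])
    assert res.total_assigned == lib.total_clean, "tag conservation violated"
    assert sum(res.sense_counts.values()) == res.unique_sense[0]
    assert sum(res.antisense_counts.values()) == res.unique_antisense[0]
    return res


def write_clean_tsv(lib: CleanTagLibrary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(lib.counts):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")


def read_clean_tsv(path: str, sample_id: str | None = None) -> CleanTagLibrary:
    lib = CleanTagLibrary(sample_id=sample_id or Path(path).stem.split(".")[0])
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tag\t"):
            raise ValueError(f"{path}: not a clean-tag TSV")
        for line in fh:
            tag, count = line.split("\t")
            lib.counts[tag] = int(count)
    return lib


def write_mapping_tsv(res: MappingResult, path: str) -> None:
    genes = sorted(set(res.sense_counts) | set(res.antisense_counts))
    with open(path, "w") as fh:
        fh.write("gene_id\tsense_count\tantisense_count\n")
        for g in genes:
            fh.write(f"{g}\t{res.sense_counts.get(g, 0)}\t{res.antisense_counts.get(g, 0)}\n")
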