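"""TPM normalization, the stranded expression matrix, and NAT profiling.

Expression of a gene in a library is the sum of its uniquely mapped tag
counts, normalized to TPM — transcripts per million clean tags:
``count / total_clean * 1e6``.  Because ambiguous and unknown tags are not
assigned, the TPM of all genes and both strands in a sample sums to at
most one million, with equality exactly when every clean tag was assigned.

The NAT profile summarizes antisense transcription per sample: how many
genes show any antisense signal (as a fraction of the reference gene set),
the sense:antisense ratios of total tags, distinct tags and detected
genes, and the Spearman rank correlation between sense and antisense
expression across genes detected on both strands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .refdb import percentage
from .tags import CleanTagLibrary, MappingResult


@dataclass
class StrandedExpressionMatrix:
    """genes x samples counts and TPM in two strand layers."""

    counts_sense: pd.DataFrame
    counts_antisense: pd.DataFrame
    tpm_sense: pd.DataFrame
    tpm_antisense: pd.DataFrame
    total_clean: dict[str, int]

    @property
    def genes(self) -> list[str]:
        return list(self.counts_sense.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts_sense.columns)

    def layer(self, name: str, tpm: bool = True) -> pd.DataFrame:
        if name == "sense":
            return self.tpm_sense if tpm else self.counts_sense
        if name == "antisense":
            return self.tpm_antisense if tpm else self.counts_antisense
        raise KeyError(name)


def tpm_normalize(count: float, total_clean: int) -> float:
    """TPM = count / total clean tags in the sample * 1,000,000."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive for TPM normalization")
    return count / total_clean * 1_000_000


def build_matrix(
    mappings: list[MappingResult],
    totals: dict[str, int],
    genes: list[str],
) -> StrandedExpressionMatrix:
    """Assemble per-sample mapping results into the stranded matrix.

    ``totals`` maps sample_id -> total clean tags (the TPM denominator);
    ``genes`` fixes the row universe (the reference gene list).
    """
    samples = [m.sample_id for m in mappings]
    cs = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    ca = cs.copy()
    for m in mappings:
        for g, v in m.sense_counts.items():
            cs.loc[g, m.sample_id] = v
        for g, v in m.antisense_counts.items():
            ca.loc[g, m.sample_id] = v
    denom = pd.Series({s: totals[s] for s in samples}, dtype=float)
    if (denom <= 0).any():
        raise ValueError("total_clean must be positive for every sample")
    ts = cs / denom * 1e6
    ta = ca / denom * 1e6
    return StrandedExpressionMatrix(
        counts_sense=cs,
        counts_antisense=ca,
        tpm_sense=ts,
        tpm_antisense=ta,
        total_clean={s: int(totals[s]) for s in samples},
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def mapping_summary_row(
    sample_id: str,
    layer: str,
    unambiguous_total: int,
    clean_total: int,
    unambiguous_distinct: int,
    clean_distinct: int,
    genes_detected: int,
    n_ref_genes: int,
) -> dict:
    """One mapping-summary row from plain integer counts (percentages to 2 dp)."""
    return {
        "sample_id": sample_id,
        "layer": layer,
        "unambiguous_total": unambiguous_total,
        "pct_of_clean_total": percentage(unambiguous_total, clean_total),
        "unambiguous_distinct": unambiguous_distinct,
        "pct_of_clean_distinct": percentage(unambiguous_distinct, clean_distinct),
        "genes_detected": genes_detected,
        "pct_of_ref_genes": percentage(genes_detected, n_ref_genes),
    }


def summarize_library(
    mapping: MappingResult,
    clean: CleanTagLibrary,
    n_ref_genes: int,
    layer: str = "sense",
) -> dict:
    """One summary row per sample, in the shape of the published mapping tables.

    For the requested strand layer: total and distinct uniquely mapped tag
    counts with their percentages of the clean totals, plus detected-gene
    count as a percentage of the reference gene set.
    """
    if mapping.sample_id != clean.sample_id:
        raise ValueError(
            f"sample mismatch: mapping {mapping.sample_id!r} vs clean {clean.sample_id!r}"
        )
    if layer == "sense":
        total, distinct = mapping.unique_sense
        n_genes = mapping.n_genes_sense_detected
    elif layer == "antisense":
        total, distinct = mapping.unique_antisense
        n_genes = mapping.n_genes_antisense_detected
    else:
        raise KeyError(layer)
    return mapping_summary_row(
        mapping.sample_id,
        layer,
        total,
        clean.total_clean,
        distinct,
        clean.distinct_clean,
        n_genes,
        n_ref_genes,
    )


@dataclass
class NatProfile:
    per_sample: pd.DataFrame  # one row per sample
    warnings: list[str] = field(default_factory=list)


def _ratio(a: float, b: float) -> float:
    return a / b if b else math.inf


def nat_profile(
    matrix: StrandedExpressionMatrix,
    mappings: list[MappingResult],
    n_ref_genes: int,
) -> NatProfile:
    """Per-sample antisense-transcription summary.

    Spearman correlation is computed across genes detected on *both*
    strands in that sample (restricting avoids the zero-inflation artifact
    of including one-strand-only genes).  With zero antisense tags the
    ratios degrade to an infinite sentinel with a warning.
    """
    rows = []
    notes: list[str] = []
    by_id = {m.sample_id: m for m in mappings}
    for s in matrix.samples:
        m = by_id[s]
        anti = matrix.counts_antisense[s]
        sense = matrix.counts_sense[s]
        n_nat = int((anti > 0).sum())
        if m.unique_antisense[0] == 0:
            msg = f"{s}: no antisense tags; sense:antisense ratios are infinite"
            notes.append(msg)
            warnings.warn(msg)
        both = (sense > 0) & (anti > 0)
        if both.sum() >= 2:
            r = spearman(matrix.tpm_sense.loc[both, s], matrix.tpm_antisense.loc[both, s])
        else:
            r = math.nan
        rows.append(
            {
                "sample_id": s,
                "n_genes_with_nat": n_nat,
                "pct_genes_with_nat": percentage(n_nat, n_ref_genes),
                "ratio_total_tags": _ratio(m.unique_sense[0], m.unique_antisense[0]),
                "ratio_distinct_tags": _ratio(m.unique_sense[1], m.unique_antisense[1]),
                "ratio_genes": _ratio(
                    m.n_genes_sense_detected, m.n_genes_antisense_detected
                ),
                "n_genes_both_strands": int(both.sum()),
                "spearman_r": r,
            }
        )
    return NatProfile(per_sample=pd.DataFrame(rows), warnings=notes)


def format_ratio(x: float) -> str:
    """Nearest-integer 'a:b' rendering of a ratio, for report output."""
    if math.isinf(x):
        return "inf"
    if x >= 1:
        return f"{round(x)}:1"
    return f"1:{round(1 / x)}" if x > 0 else "0:1"
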