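"""Bundled summary tables from a published sheep-skin DGE study.

The package ships the printed summary statistics of a tag-based digital
gene expression study of sheep skin comparing a super-fine wool group (S)
to a fine wool group (F), three animals each: per-library tag totals, the
sense and antisense unambiguous-mapping summaries, the reference-tag
database statistics, and the 47 reported differentially expressed
transcripts (40 genes + 7 natural antisense transcripts) with their
log2 ratios and noise-dominance probabilities.  These tables let the
percentage arithmetic and the significance filter be replayed without the
underlying raw sequencing data.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .diffexpr import DeRecord


def _data_path(name: str):
    return resources.files("tagnat").joinpath("data", name)


def load_library_summary() -> pd.DataFrame:
    """Per-sample raw/clean tag totals (total and distinct)."""
    with resources.as_file(_data_path("library_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_mapping_summary(layer: str = "sense") -> pd.DataFrame:
    """Per-sample unambiguous mapping counts for one strand layer."""
    name = {"sense": "sense_mapping_summary.tsv", "antisense": "antisense_mapping_summary.tsv"}[
        layer
    ]
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t")


def load_refdb_summary() -> dict:
    """Reference-tag database counts (genes and tags, total vs. unambiguous)."""
    with resources.as_file(_data_path("refdb_summary.json")) as p:
        return json.loads(p.read_text())


def load_de_table() -> pd.DataFrame:
    """The 47 reported DE transcripts: layer, id, log2 ratio, probability."""
    with resources.as_file(_data_path("de_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"transcript_id": str})


def de_table_records(min_tpm: float = 1.0) -> list[DeRecord]:
    """The reported DE rows as records ready for the significance filter.

    Only log2 ratio and probability are printed; condition means are not,
    so both means are set to ``min_tpm`` (the reported rows already passed
    the expression floor upstream) and D is left at 0.
    """
    records = []
    for row in load_de_table().itertuples(index=False):
        records.append(
            DeRecord(
                transcript_id=str(row.transcript_id),
                layer=row.layer,
                mean_tpm_S=min_tpm,
                mean_tpm_F=min_tpm,
                M=float(row.log2_ratio),
                D=0.0,
                probability=float(row.probability),
            )
        )
    return records
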