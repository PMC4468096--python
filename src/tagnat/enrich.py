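"""Hypergeometric term enrichment with Benjamini–Hochberg correction.

For a term annotating ``M_term`` of the ``N`` annotated background genes,
of which ``m`` fall in the ``n`` annotated significant genes, the raw
enrichment P-value is the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M_term, i) C(N - M_term, n - i) / C(N, n)
      = P(X >= m),

computed with exact integer arithmetic.  Terms with m = 0 are not tested
(they cannot be enriched and would only dilute the multiple-testing
budget); raw P-values across tested terms are Benjamini–Hochberg adjusted
and flagged significant at an adjusted P <= 0.05 by default.

The gene→term map is taken as flat and already propagated; no ontology
hierarchy is traversed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class EnrichmentTerm:
    term_id: str
    term_label: str
    N: int
    M_term: int
    n: int
    m: int
    p_raw: float
    p_adjusted: float = 1.0
    significant: bool = False


def hypergeom_tail_p(N: int, M_term: int, n: int, m: int) -> float:
    """Upper-tail P(X >= m) for X ~ Hypergeometric(N, M_term, n), exact."""
    for name, v in (("N", N), ("M_term", M_term), ("n", n), ("m", m)):
        if not isinstance(v, (int,)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if M_term > N or n > N or m > n or m > M_term:
        if m > min(M_term, n):
            raise ValueError(
                f"inconsistent counts: m={m} exceeds min(M_term={M_term}, n={n})"
            )
        raise ValueError(f"inconsistent counts: N={N}, M_term={M_term}, n={n}, m={m}")
    if m == 0:
        return 1.0
    total = comb(N, n)
    below = sum(comb(M_term, i) * comb(N - M_term, n - i) for i in range(m))
    return float((total - below) / total)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted P-values, input order preserved."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {p}")
    n = len(ps)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: ps[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, ps[i] * n / (rank + 1))
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def enrich(
    significant: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, set[str]] | pd.DataFrame,
    term_labels: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentTerm]:
    """Test every term with at least one significant member.

    ``term_map`` is either gene_id -> set of term ids, or a DataFrame with
    ``gene_id``/``term_id`` (and optionally ``term_label``) columns.  The
    universe is restricted to annotated genes: N counts annotated
    background genes, n annotated significant genes.  Results are sorted by
    adjusted then raw P.
    """
    labels = dict(term_labels or {})
    if isinstance(term_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for row in term_map.itertuples(index=False):
            mapping.setdefault(row.gene_id, set()).add(row.term_id)
            if hasattr(row, "term_label"):
                labels.setdefault(row.term_id, row.term_label)
        term_map = mapping

    background = set(background)
    significant = set(significant)
    if not significant <= background:
        raise ValueError("significant genes must be a subset of the background")
    annotated = {g for g in background if term_map.get(g)}
    sig_annotated = significant & annotated
    if not sig_annotated:
        warnings.warn("no annotated gene in the significant set; nothing to test")
        return []

    N = len(annotated)
    n = len(sig_annotated)
    by_term: dict[str, tuple[int, int]] = {}
    for g in annotated:
        in_sig = g in sig_annotated
        for t in term_map[g]:
            M_t, m_t = by_term.get(t, (0, 0))
            by_term[t] = (M_t + 1, m_t + int(in_sig))

    tested = [
        EnrichmentTerm(
            term_id=t,
            term_label=labels.get(t, t),
            N=N,
            M_term=M_t,
            n=n,
            m=m_t,
            p_raw=hypergeom_tail_p(N, M_t, n, m_t),
        )
        for t, (M_t, m_t) in sorted(by_term.items())
        if m_t >= 1
    ]
    adjusted = bh_adjust([e.p_raw for e in tested])
    for e, pa in zip(tested, adjusted):
        e.p_adjusted = pa
        e.significant = pa <= alpha
    tested.sort(key=lambda e: (e.p_adjusted, e.p_raw, e.term_id))
    return tested


def enrichment_frame(terms: list[EnrichmentTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [e.term_id for e in terms],
            "term_label": [e.term_label for e in terms],
            "N": [e.N for e in terms],
            "M_term": [e.M_term for e in terms],
            "n": [e.n for e in terms],
            "m": [e.m for e in terms],
            "p_raw": [e.p_raw for e in terms],
            "p_adjusted": [e.p_adjusted for e in terms],
            "significant": [e.significant for e in terms],
        }
    )


def read_term_map(path: str) -> pd.DataFrame:
    """gene→term TSV: gene_id, term_id[, term_label[, namespace]]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "term_id" not in df.columns:
        raise ValueError(f"{path}: need gene_id and term_id columns")
    return df
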