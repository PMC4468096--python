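import logging
import re

import numpy as np
import pytest

from tagnat import refdb, simulate

logging.getLogger("tagnat").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_genome():
    return simulate.generate_genome(60, (150, 400), 0.9, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return simulate.assign_expression(
        small_genome, n_de=6, effect_log2=2.0, nat_fraction=0.4, nat_corr=0.6, seed=7,
        n_de_nat=2,
    )


@pytest.fixture(scope="session")
def small_db(small_genome):
    return refdb.build_reference_db(small_genome.genes)


@pytest.fixture(scope="session")
def small_library(small_genome, small_truth):
    return simulate.simulate_library(
        small_genome, small_truth, "S1", "S", depth=30_000, error_rate=0.0, seed=3
    )


def brute_force_tags(sequence: str):
    """Independent regex scan for CATG+17 windows on one strand."""
    out = []
    for m in re.finditer(r"(?=(CATG[ACGTN]{17}))", sequence):
        out.append((m.group(1), m.start()))
    return [(t, o) for t, o in out if "N" not in t]


def brute_force_map(tag: str, ref_entries: dict, max_mismatch: int = 1):
    """Quadratic Hamming-scan oracle mirroring the mapping rules.

    ``ref_entries``: tag -> list of (gene_id, strand_relation) pairs.
    Returns ("assigned", pair) | ("ambiguous", None) | ("unknown", None).
    """

    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    exact = ref_entries.get(tag)
    if exact is not None:
        pairs = set(exact)
        if len(pairs) == 1:
            return "assigned", next(iter(pairs))
        return "ambiguous", None
    if max_mismatch >= 1:
        hits = set()
        for ref_tag, pairs in ref_entries.items():
            if len(set(pairs)) != 1:
                continue  # only unambiguous reference tags are searched
            if hamming(tag, ref_tag) <= max_mismatch:
                hits.add(next(iter(set(pairs))))
        if len(hits) == 1:
            return "assigned", next(iter(hits))
        if hits:
            return "ambiguous", None
    return "unknown", None


@pytest.fixture
def rng():
    return np.random.default_rng(0)
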