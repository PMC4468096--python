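import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tagnat.enrich import EnrichmentTerm, bh_adjust, enrich, hypergeom_tail_p


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail_p(20, 5, 5, 0) == 1.0

    def test_term_covering_whole_background_is_certain(self):
        assert hypergeom_tail_p(20, 20, 5, 3) == 1.0

    def test_hand_enumerated_example(self):
        # C(5,3)C(15,2) + C(5,4)C(15,1) + C(5,5)C(15,0) over C(20,5)
        assert hypergeom_tail_p(20, 5, 5, 3) == pytest.approx(1126 / 15504)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_tail_p(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeom_tail_p(10, 5, 3, 4)

    def test_matches_exhaustive_enumeration_for_small_universes(self):
        # enumerate every n-subset of an N-gene universe and count draws
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    genes = range(N)
                    term = set(range(M))
                    total = math.comb(N, n)
                    tail_counts = {}
                    for draw in itertools.combinations(genes, n):
                        m = len(term & set(draw))
                        tail_counts[m] = tail_counts.get(m, 0) + 1
                    for m in range(min(M, n) + 1):
                        expected = sum(c for mm, c in tail_counts.items() if mm >= m) / total
                        assert hypergeom_tail_p(N, M, n, m) == pytest.approx(expected)

    def test_cross_check_against_scipy_survival(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            N = int(rng.integers(10, 2000))
            M = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(0, min(M, n) + 1))
            assert hypergeom_tail_p(N, M, n, m) == pytest.approx(
                stats.hypergeom.sf(m - 1, N, M, n), rel=1e-9, abs=1e-12
            )

    def test_tail_nonincreasing_in_m(self):
        vals = [hypergeom_tail_p(50, 12, 9, m) for m in range(10)]
        assert vals == sorted(vals, reverse=True)

    def test_point_masses_from_successive_tails_sum_to_one(self):
        N, M, n = 30, 9, 7
        top = min(M, n)
        tail = lambda m: hypergeom_tail_p(N, M, n, m) if m <= top else 0.0
        masses = [tail(m) - tail(m + 1) for m in range(top + 1)]
        assert sum(masses) == pytest.approx(1.0)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.037]) == [0.037]

    def test_equal_values_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_known_sequence_matches_independent_stepup(self):
        ps = [0.01, 0.02, 0.03, 0.5]
        assert bh_adjust(ps) == pytest.approx(
            list(multipletests(ps, method="fdr_bh")[1])
        )

    def test_random_inputs_match_statsmodels(self, rng):
        for _ in range(20):
            ps = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(list(ps)) == pytest.approx(
                list(multipletests(ps, method="fdr_bh")[1])
            )

    def test_input_order_preserved(self):
        ps = [0.5, 0.001, 0.03]
        adj = bh_adjust(ps)
        assert adj[1] < adj[2] < adj[0]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_stepup_properties_hold_for_arbitrary_inputs(self, ps):
        adj = bh_adjust(ps)
        assert all(0.0 <= a <= 1.0 for a in adj)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        # rank order of adjusted values never contradicts the raw order
        for (pi, ai), (pj, aj) in itertools.combinations(zip(ps, adj), 2):
            if pi < pj:
                assert ai <= aj + 1e-12
        assert adj == pytest.approx(list(multipletests(ps, method="fdr_bh")[1]))


def _toy_universe():
    background = [f"g{i}" for i in range(30)]
    term_map = {}
    for i, g in enumerate(background):
        terms = set()
        if i < 10:
            terms.add("T1")
        if i % 3 == 0:
            terms.add("T2")
        if i >= 25:
            terms.add("T3")
        if terms:
            term_map[g] = terms
    significant = ["g0", "g1", "g2", "g3", "g27", "g28"]
    return significant, background, term_map


class TestEnrich:
    def test_toy_universe_matches_direct_formula(self):
        significant, background, term_map = _toy_universe()
        result = enrich(significant, background, term_map)
        annotated = [g for g in background if term_map.get(g)]
        sig_annot = [g for g in significant if g in annotated]
        N, n = len(annotated), len(sig_annot)
        raw = {}
        for t in ("T1", "T2", "T3"):
            M = sum(1 for g in annotated if t in term_map[g])
            m = sum(1 for g in sig_annot if t in term_map[g])
            if m >= 1:
                raw[t] = float(stats.hypergeom.sf(m - 1, N, M, n))
        adj = dict(zip(sorted(raw), multipletests([raw[t] for t in sorted(raw)], method="fdr_bh")[1]))
        assert {e.term_id for e in result} == set(raw)
        for e in result:
            assert e.N == N and e.n == n
            assert e.p_raw == pytest.approx(raw[e.term_id])
            assert e.p_adjusted == pytest.approx(adj[e.term_id])
            assert e.p_adjusted >= e.p_raw - 1e-12

    def test_sorted_by_adjusted_p(self):
        significant, background, term_map = _toy_universe()
        result = enrich(significant, background, term_map)
        ps = [e.p_adjusted for e in result]
        assert ps == sorted(ps)

    def test_exclusive_term_gets_smallest_possible_p(self):
        background = [f"g{i}" for i in range(12)]
        term_map = {g: {"BG"} for g in background}
        sig = ["g0", "g1", "g2"]
        for g in sig:
            term_map[g] = {"BG", "HIT"}
        result = {e.term_id: e for e in enrich(sig, background, term_map)}
        assert result["HIT"].p_raw == pytest.approx(
            stats.hypergeom.sf(2, 12, 3, 3)
        )
        assert result["HIT"].p_raw <= result["BG"].p_raw

    def test_unannotated_significant_set_is_empty_with_warning(self):
        background = ["a", "b", "c"]
        term_map = {"b": {"T"}}
        with pytest.warns(UserWarning, match="no annotated"):
            assert enrich(["a"], background, term_map) == []

    def test_terms_without_significant_member_not_tested(self):
        significant, background, term_map = _toy_universe()
        term_map["g20"] = {"LONELY"}
        result = enrich(significant, background, term_map)
        assert "LONELY" not in {e.term_id for e in result}

    def test_dataframe_term_map_accepted(self):
        significant, background, term_map = _toy_universe()
        rows = [
            {"gene_id": g, "term_id": t, "term_label": f"label {t}"}
            for g, ts in term_map.items()
            for t in ts
        ]
        result = enrich(significant, background, pd.DataFrame(rows))
        assert {e.term_label for e in result} == {"label T1", "label T2", "label T3"}

    def test_significant_outside_background_raises(self):
        with pytest.raises(ValueError, match="subset"):
            enrich(["x"], ["a"], {"a": {"T"}})
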