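import math
from dataclasses import dataclass

import numpy as np
import pytest

from tagnat import tags
from tagnat.refdb import TAG_LEN, ReferenceTag, ReferenceTagDB
from tagnat.simulate import DEFAULT_ADAPTER

from conftest import brute_force_map

ADAPTER = DEFAULT_ADAPTER


def _read(tag, filler="G"):
    r = tag + ADAPTER
    return r + filler * (35 - len(r))


def _make_db(assignments):
    """assignments: list of (tag, gene_id, strand_relation)."""
    entries = {}
    for tag, gene, strand in assignments:
        entries.setdefault(tag, []).append(ReferenceTag(tag, gene, strand, (0,)))
    return ReferenceTagDB(entries=entries)


TAG_A = "CATG" + "A" * 17
TAG_C = "CATG" + "C" * 17


class TestCleanReads:
    def test_identical_reads_counted_once(self):
        lib = tags.clean_reads([_read(TAG_A)] * 3, adapter=ADAPTER)
        assert lib.counts == {TAG_A: 3}
        assert lib.total_clean == 3 and lib.distinct_clean == 1

    def test_singleton_dropped_and_counted(self):
        lib = tags.clean_reads([_read(TAG_A)] * 3 + [_read(TAG_C)], adapter=ADAPTER)
        assert TAG_C not in lib.counts
        assert lib.dropped["singleton"] == 1

    def test_singletons_kept_when_disabled(self):
        lib = tags.clean_reads([_read(TAG_C)], adapter=ADAPTER, drop_singletons=False)
        assert lib.counts == {TAG_C: 1}

    def test_short_insert_dropped(self):
        short = TAG_A[:20] + ADAPTER + "A"  # trims to 20 bases
        lib = tags.clean_reads([short] * 2, adapter=ADAPTER)
        assert lib.counts == {}
        assert lib.dropped["too_short"] == 2

    def test_adapter_only_read_dropped_as_empty(self):
        lib = tags.clean_reads([ADAPTER + "G" * (35 - len(ADAPTER))], adapter=ADAPTER)
        assert lib.dropped["empty"] == 1

    def test_partial_adapter_at_end_is_trimmed(self):
        read = TAG_A + ADAPTER[:7]  # 28 bases, truncated adapter
        lib = tags.clean_reads([read] * 2, adapter=ADAPTER)
        assert lib.counts == {TAG_A: 2}

    def test_malformed_fastq_names_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\n")  # truncated record
        with pytest.raises(ValueError, match=r"index \d+"):
            tags.clean_reads(str(p), adapter=ADAPTER)

    def test_mean_quality_filter(self, tmp_path):
        p = tmp_path / "q.fastq"
        good = _read(TAG_A)
        p.write_text(f"@a\n{good}\n+\n{'I' * 35}\n@b\n{good}\n+\n{'#' * 35}\n")
        lib = tags.clean_reads(str(p), adapter=ADAPTER, min_mean_quality=20, drop_singletons=False)
        assert lib.total_clean == 1
        assert lib.dropped["low_quality"] == 1


class TestSaturationCurve:
    def test_endpoints(self, small_library):
        lib = tags.clean_reads(small_library, adapter=ADAPTER)
        curve = tags.saturation_curve(lib, n_points=5, seed=1)
        assert curve[0] == (0, 0)
        assert curve[-1] == (lib.total_clean, lib.distinct_clean)

    def test_monotone_nondecreasing(self, small_library):
        lib = tags.clean_reads(small_library, adapter=ADAPTER)
        curve = tags.saturation_curve(lib, n_points=9, seed=2)
        depths = [d for d, _ in curve]
        distinct = [k for _, k in curve]
        assert depths == sorted(depths)
        assert distinct == sorted(distinct)

    def test_rare_tag_detection_matches_hypergeometric(self):
        # library {A:1000, B:1}; at half depth the rare tag is drawn with
        # P = 1 - C(1000,500)/C(1001,500) = 500/1001 (hypergeometric one-miss)
        lib = tags.CleanTagLibrary("s", counts={TAG_A: 1000, TAG_C: 1})
        p_expected = 1 - math.comb(1000, 500) / math.comb(1001, 500)
        mean_extra = np.mean(
            [tags.saturation_curve(lib, n_points=3, seed=s)[1][1] - 1 for s in range(400)]
        )
        assert mean_extra == pytest.approx(p_expected, abs=0.07)

    def test_requires_two_points(self, small_library):
        lib = tags.clean_reads(small_library, adapter=ADAPTER)
        with pytest.raises(ValueError):
            tags.saturation_curve(lib, n_points=1)


class TestMapTags:
    def test_exact_unique_hit_adds_count(self):
        db = _make_db([(TAG_A, "g1", "sense")])
        lib = tags.CleanTagLibrary("s", counts={TAG_A: 7})
        res = tags.map_tags(lib, db)
        assert res.sense_counts == {"g1": 7}
        assert res.unique_sense == (7, 1)

    def test_shared_reference_tag_discarded_as_ambiguous(self):
        db = _make_db([(TAG_A, "g1", "sense"), (TAG_A, "g2", "sense")])
        lib = tags.CleanTagLibrary("s", counts={TAG_A: 5})
        res = tags.map_tags(lib, db)
        assert res.ambiguous_discarded == (5, 1)
        assert res.sense_counts == {}

    def test_one_mismatch_rescues_to_unique_gene(self):
        db = _make_db([(TAG_A, "g1", "antisense")])
        mutated = "CATG" + "A" * 16 + "T"
        lib = tags.CleanTagLibrary("s", counts={mutated: 4})
        res = tags.map_tags(lib, db)
        assert res.antisense_counts == {"g1": 4}
        status, pair = brute_force_map(mutated, {TAG_A: [("g1", "antisense")]})
        assert status == "assigned" and pair == ("g1", "antisense")

    def test_mismatch_to_two_genes_is_ambiguous(self):
        t1 = "CATG" + "A" * 16 + "T"
        t2 = "CATG" + "A" * 16 + "G"
        db = _make_db([(t1, "g1", "sense"), (t2, "g2", "sense")])
        lib = tags.CleanTagLibrary("s", counts={TAG_A: 2})
        res = tags.map_tags(lib, db)
        assert res.ambiguous_discarded == (2, 1)

    def test_exact_hit_beats_mismatch_candidates(self):
        t1 = "CATG" + "A" * 16 + "T"  # Hamming-1 neighbor of TAG_A
        db = _make_db([(TAG_A, "g1", "sense"), (t1, "g2", "sense")])
        lib = tags.CleanTagLibrary("s", counts={TAG_A: 3})
        res = tags.map_tags(lib, db)
        assert res.sense_counts == {"g1": 3}

    def test_no_hit_is_unknown(self):
        db = _make_db([(TAG_A, "g1", "sense")])
        far = "CATG" + "G" * 17
        lib = tags.CleanTagLibrary("s", counts={far: 9})
        res = tags.map_tags(lib, db)
        assert res.unknown == (9, 1)

    def test_mismatch_disabled(self):
        db = _make_db([(TAG_A, "g1", "sense")])
        mutated = "CATG" + "A" * 16 + "T"
        lib = tags.CleanTagLibrary("s", counts={mutated: 1})
        res = tags.map_tags(lib, db, max_mismatch=0)
        assert res.unknown == (1, 1)

    def test_wrong_tag_length_raises(self):
        db = _make_db([(TAG_A, "g1", "sense")])
        lib = tags.CleanTagLibrary("s", counts={"CATG": 1})
        with pytest.raises(ValueError, match="length"):
            tags.map_tags(lib, db)

    def test_conservation_partition(self, small_library, small_db):
        lib = tags.clean_reads(small_library, adapter=ADAPTER)
        res = tags.map_tags(lib, small_db)
        assert (
            res.unique_sense[0]
            + res.unique_antisense[0]
            + res.ambiguous_discarded[0]
            + res.unknown[0]
            == lib.total_clean
        )
        assert (
            res.unique_sense[1]
            + res.unique_antisense[1]
            + res.ambiguous_discarded[1]
            + res.unknown[1]
            == lib.distinct_clean
        )

    def test_agrees_with_brute_force_oracle_on_random_libraries(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(25):
            n_ref = int(rng.integers(20, 120))
            ref_tags = [
                "CATG" + "".join(rng.choice(bases, size=17)) for _ in range(n_ref)
            ]
            assignments = [
                (t, f"g{int(rng.integers(0, 30))}", rng.choice(["sense", "antisense"]))
                for t in ref_tags
            ]
            db = _make_db(assignments)
            ref_entries = {
                t: [(r.gene_id, r.strand_relation) for r in refs]
                for t, refs in db.entries.items()
            }
            observed = {}
            for _ in range(int(rng.integers(10, 60))):
                base = ref_tags[int(rng.integers(0, n_ref))]
                n_mut = int(rng.integers(0, 3))
                t = list(base)
                for _ in range(n_mut):
                    i = int(rng.integers(0, 21))
                    t[i] = rng.choice(bases)
                observed["".join(t)] = observed.get("".join(t), 0) + int(rng.integers(1, 5))
            lib = tags.CleanTagLibrary("s", counts=observed)
            res = tags.map_tags(lib, db)
            exp_sense, exp_anti, exp_amb, exp_unk = {}, {}, 0, 0
            for t, c in observed.items():
                status, pair = brute_force_map(t, ref_entries)
                if status == "assigned":
                    gene, strand = pair
                    d = exp_sense if strand == "sense" else exp_anti
                    d[gene] = d.get(gene, 0) + c
                elif status == "ambiguous":
                    exp_amb += c
                else:
                    exp_unk += c
            assert res.sense_counts == exp_sense
            assert res.antisense_counts == exp_anti
            assert res.ambiguous_discarded[0] == exp_amb
            assert res.unknown[0] == exp_unk


def test_clean_tsv_round_trip(small_library, tmp_path):
    lib = tags.clean_reads(small_library, adapter=ADAPTER)
    path = tmp_path / "clean.tsv"
    tags.write_clean_tsv(lib, str(path))
    back = tags.read_clean_tsv(str(path))
    assert back.counts == lib.counts
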