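"""Unit tests for chimeric read-pair demultiplexing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redc.chimera import (
    ReadPair,
    deduplicate_pairs,
    first_low_quality_position,
    prepare_dna_for_mapping,
    rightmost_complementarity_trim,
    scan_oligo,
    split_read_pair,
)
from redc.oligos import DEFAULT_CATALOG, STO_READTHROUGH, revcomp

BRIDGE = DEFAULT_CATALOG.bridge_r1
Q37 = lambda n: [37] * n  # noqa: E731


def _pair(pid, r1, r2, q1=None, q2=None):
    return ReadPair(pid, r1, r2, q1 or Q37(len(r1)), q2 or Q37(len(r2)))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDeduplication:
    def test_byte_identical_pairs_collapse(self, rng):
        r1, r2 = _random_seq(rng, 80), _random_seq(rng, 80)
        pairs = [_pair("a", r1, r2), _pair("b", r1, r2)]
        kept = list(deduplicate_pairs(pairs))
        assert [p.id for p in kept] == ["a"]

    def test_key_uses_first_50_nt_only(self, rng):
        r1, r2 = _random_seq(rng, 80), _random_seq(rng, 80)
        r1_b = r1[:60] + ("A" if r1[60] != "A" else "C") + r1[61:]
        kept = list(deduplicate_pairs([_pair("a", r1, r2), _pair("b", r1_b, r2)]))
        assert [p.id for p in kept] == ["a"]

    def test_distinct_prefixes_both_retained(self, rng):
        r1, r2 = _random_seq(rng, 80), _random_seq(rng, 80)
        r1_b = r1[:10] + ("A" if r1[10] != "A" else "C") + r1[11:]
        kept = list(deduplicate_pairs([_pair("a", r1, r2), _pair("b", r1_b, r2)]))
        assert [p.id for p in kept] == ["a", "b"]

    def test_idempotent(self, rng):
        pairs = [_pair(f"p{i}", _random_seq(rng, 60), _random_seq(rng, 60))
                 for i in range(20)]
        pairs += pairs[:5]
        once = list(deduplicate_pairs(pairs))
        twice = list(deduplicate_pairs(once))
        assert [p.id for p in once] == [p.id for p in twice]


class TestQualityWindow:
    def test_all_high_quality_passes(self):
        assert first_low_quality_position([30] * 50) is None

    def test_all_low_quality_is_position_zero(self):
        assert first_low_quality_position([2] * 50) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        qual = rng.integers(2, 41, size=120).tolist()
        window, thr = 5, 26
        expected = None
        for i in range(len(qual) - window + 1):
            if sum(qual[i:i + window]) / window < thr:
                expected = i
                break
        assert first_low_quality_position(qual, window, thr) == expected


class TestOligoScan:
    def test_exact_bridge_hit(self, rng):
        seq = _random_seq(rng, 5) + BRIDGE + _random_seq(rng, 10)
        hits = scan_oligo(seq, BRIDGE, 1, protected_suffix_len=2)
        assert (5, 0) in hits

    def test_one_internal_mismatch_allowed(self):
        mutated = "T" + BRIDGE[1:]
        assert mutated != BRIDGE
        hits = scan_oligo("AAA" + mutated + "CC", BRIDGE, 1, protected_suffix_len=2)
        assert hits == [(3, 1)]

    def test_protected_suffix_rejects_ga_mismatch(self):
        mutated = BRIDGE[:-1] + "C"  # mismatch inside the terminal GA
        assert scan_oligo("AAA" + mutated, BRIDGE, 1, protected_suffix_len=2) == []

    def test_n_counts_as_mismatch(self):
        seq = BRIDGE[:10] + "N" + BRIDGE[11:]
        assert scan_oligo(seq, BRIDGE, 0) == []
        assert scan_oligo(seq, BRIDGE, 1) == [(0, 1)]

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_brute_force_hamming(self, seed):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, 200)
        pattern = _random_seq(rng, 6)
        expected = []
        for i in range(len(seq) - len(pattern) + 1):
            d = sum(a != b for a, b in zip(seq[i:i + len(pattern)], pattern))
            if d <= 1:
                expected.append((i, d))
        assert scan_oligo(seq, pattern, 1) == expected


class TestComplementarityTrim:
    SOURCE = "ACGTACGTACGTAA"

    def test_internal_occurrence_trims_after_match(self):
        seq = "GGGG" + revcomp(self.SOURCE) + "CCTT"
        assert rightmost_complementarity_trim(seq, self.SOURCE) == 18

    def test_no_occurrence_no_trim(self):
        assert rightmost_complementarity_trim("ACGT" * 10, self.SOURCE) is None

    def test_occurrence_at_end_is_noop(self):
        seq = "GGGG" + revcomp(self.SOURCE)
        assert rightmost_complementarity_trim(seq, self.SOURCE) is None

    def test_rightmost_of_two_occurrences_wins(self):
        rc = revcomp(self.SOURCE)
        seq = rc + "TTTT" + rc + "CC"
        assert rightmost_complementarity_trim(seq, self.SOURCE) == len(seq) - 2


class TestSplitReadPair:
    def _reads(self, rng, dna_len=20, rna_len=30, read_len=100):
        dna = _random_seq(rng, dna_len)
        rna = _random_seq(rng, rna_len)
        r1 = (dna + BRIDGE + revcomp(rna) + STO_READTHROUGH + "A" * read_len)[:read_len]
        r2 = ("GGG" + rna + revcomp(BRIDGE) + revcomp(dna) + "A" * read_len)[:read_len]
        return dna, rna, r1, r2

    def test_recovers_parts_of_expected_lengths(self, rng):
        dna, rna, r1, r2 = self._reads(rng)
        out = split_read_pair(_pair("x", r1, r2))
        assert out.rejection_reason == "none"
        assert out.dna_seq == dna
        assert out.rna3_seq == revcomp(rna)
        assert out.rna5_seq == rna
        assert (len(out.dna_seq), len(out.rna3_seq), len(out.rna5_seq)) == (20, 30, 30)

    def test_short_sto_stub_removed_by_complementarity(self, rng):
        # leave only 6 nt of read-through: too short for the probe scan
        dna, rna, r1, r2 = self._reads(rng, dna_len=20, rna_len=37)
        assert len(dna) + 37 + len(rna) + 6 == 100
        out = split_read_pair(_pair("x", r1, r2))
        assert out.rna3_seq == revcomp(rna)
        assert out.rna5_seq == rna

    def test_missing_ggg_rejected(self, rng):
        _, _, r1, r2 = self._reads(rng)
        out = split_read_pair(_pair("x", r1, "GGA" + r2[3:]))
        assert out.rejection_reason == "no_ggg"

    def test_missing_bridge_rejected(self, rng):
        _, _, _, r2 = self._reads(rng)
        out = split_read_pair(_pair("x", _random_seq(rng, 100), r2))
        assert out.rejection_reason == "no_bridge"

    def test_fully_low_quality_mate_rejected(self, rng):
        _, _, r1, r2 = self._reads(rng)
        out = split_read_pair(_pair("x", r1, r2, q1=[2] * 100))
        assert out.rejection_reason == "all_low_quality"

    def test_quality_tail_truncates_parts(self, rng):
        dna, rna, r1, r2 = self._reads(rng)
        # low-quality tail starting inside the RNA 3' region of R1
        tail = len(dna) + 37 + 10
        q1 = [37] * tail + [2] * (100 - tail)
        # brute-force the leftmost failing 5-window: the mean dips below 26
        # as soon as two low bases enter the window
        cut = next(i for i in range(96) if sum(q1[i:i + 5]) / 5 < 26)
        out = split_read_pair(_pair("x", r1, r2, q1=q1))
        assert out.dna_seq == dna
        assert out.rna3_seq == revcomp(rna)[:cut - len(dna) - 37]


class TestDnaSupplementation:
    def test_appends_catg(self):
        out = prepare_dna_for_mapping("ACGTACGTACGTACGTACGT")
        assert len(out) == 24 and out.endswith("CATG")

    def test_single_base(self):
        assert prepare_dna_for_mapping("A") == "ACATG"

    def test_empty_part_not_written(self):
        assert prepare_dna_for_mapping("") is None
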