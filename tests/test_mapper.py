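import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import migsphase as m
from migsphase.io import revcomp

dna = st.text(alphabet="ACGT", min_size=3, max_size=12)


def naive_hits(tag_seq, reference):
    """Quadratic brute-force oracle: every window, both strands."""
    out = set()
    L = len(tag_seq)
    rc = revcomp(tag_seq)
    for i in range(len(reference) - L + 1):
        window = reference[i : i + L]
        if window == tag_seq:
            out.add((i, "+"))
        if window == rc:
            out.add((i, "-"))
    return out


def naive_min_mismatch(tag_seq, reference):
    L = len(tag_seq)
    if L > len(reference):
        return None
    best = L
    for probe in (tag_seq, revcomp(tag_seq)):
        for i in range(len(reference) - L + 1):
            d = sum(a != b for a, b in zip(probe, reference[i : i + L]))
            best = min(best, d)
    return best


class TestFindOccurrences:
    def test_plus_strand_hit(self):
        hits = m.find_occurrences("ACG", "TACGT", strands=("+",))
        assert [(h.start, h.strand) for h in hits] == [(1, "+")]
        # both strands: revcomp(ACG)=CGT also occurs, at start 2
        both = m.find_occurrences("ACG", "TACGT")
        assert [(h.start, h.strand) for h in both] == [(1, "+"), (2, "-")]

    def test_both_strand_hits_sorted(self):
        hits = m.find_occurrences("CGT", "TACGT")
        assert [(h.start, h.strand) for h in hits] == [(1, "-"), (2, "+")]

    def test_absent_tag(self):
        assert m.find_occurrences("GGGG", "TACGT") == []

    def test_tag_longer_than_reference_is_empty_not_error(self):
        assert m.find_occurrences("ACGTACGT", "ACG") == []

    def test_overlapping_occurrences_found(self):
        hits = m.find_occurrences("AAA", "AAAA", strands=("+",))
        assert [h.start for h in hits] == [0, 1]

    def test_ambiguous_reference_base_never_matches(self):
        # ACGT is its own reverse complement: the N-free window hits both
        # strands, the N-containing windows hit neither
        hits = m.find_occurrences("ACGT", "ACGNACGT")
        assert [(h.start, h.strand) for h in hits] == [(4, "+"), (4, "-")]

    @given(tag=dna, ref=st.text(alphabet="ACGT", min_size=12, max_size=40))
    def test_strand_involution(self, tag, ref):
        fwd = {(h.start, h.strand) for h in m.find_occurrences(tag, ref)}
        swapped = {
            (s, "-" if st_ == "+" else "+")
            for s, st_ in (
                (h.start, h.strand) for h in m.find_occurrences(revcomp(tag), ref)
            )
        }
        assert fwd == swapped


class TestMapLibrary:
    def test_single_tag_carries_full_count(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=100))
        lib = m.Library.from_counts({ref[10:31]: 7})
        hits = m.map_library(lib, ref)
        assert len(hits) == 1 and hits[0].count == 7 and hits[0].start == 10

    def test_length_filter_excludes(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=100))
        lib = m.Library.from_counts({ref[10:31]: 7})
        assert m.map_library(lib, ref, length_filter={22}) == []

    def test_multimapping_tag_hits_every_locus(self):
        ref = "AAGGCCTTAAGGCCTT"
        lib = m.Library.from_counts({"AAGGCCTT": 5})
        hits = m.map_library(lib, ref, strands=("+",))
        assert [h.start for h in hits] == [0, 8]
        assert all(h.count == 5 for h in hits)

    def test_matches_bruteforce_on_random_library(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        counts = {}
        for _ in range(250):  # planted tags (some antisense), guaranteed hits
            pos = int(rng.integers(0, 1979))
            seq = ref[pos : pos + 21]
            seq = seq if rng.random() < 0.5 else revcomp(seq)
            counts[seq] = counts.get(seq, 0) + 1
        for _ in range(250):  # random tags, mostly absent
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 25))))
            counts[seq] = counts.get(seq, 0) + 1
        lib = m.Library.from_counts(counts)
        hits = {
            (h.tag.sequence, h.start, h.strand) for h in m.map_library(lib, ref)
        }
        expected = {
            (seq, start, strand)
            for seq in counts
            for start, strand in naive_hits(seq, ref)
        }
        assert hits == expected


class TestMinMismatch:
    def test_exact_window_is_zero(self):
        assert m.min_mismatch("ACGT", "TTACGTTT") == 0

    def test_revcomp_window_is_zero(self):
        assert m.min_mismatch("ACGT", "TT" + revcomp("ACGT") + "TT") == 0

    def test_single_substitution_is_one(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        window = ref[50:71]
        mutated = window[:10] + ("A" if window[10] != "A" else "C") + window[11:]
        assert naive_min_mismatch(mutated, ref) == 1  # no exact occurrence elsewhere
        assert m.min_mismatch(mutated, ref) == 1

    def test_tag_longer_than_reference_is_no_alignment(self):
        assert m.min_mismatch("ACGTACGT", "ACG") is None

    @given(
        tag=st.text(alphabet="ACGT", min_size=4, max_size=10),
        ref=st.text(alphabet="ACGT", min_size=10, max_size=60),
    )
    def test_zero_iff_exact_occurrence(self, tag, ref):
        mm = m.min_mismatch(tag, ref)
        has_hit = bool(m.find_occurrences(tag, ref))
        assert (mm == 0) == has_hit

    def test_matches_bruteforce(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        for _ in range(50):
            tag = "".join(rng.choice(list("ACGT"), size=21))
            assert m.min_mismatch(tag, ref) == naive_min_mismatch(tag, ref)


class TestIsSpecific:
    def test_shared_tag_is_not_specific(self):
        ref = "ACGTACGTACGTACGTACGTACGT"
        assert not m.is_specific(ref[2:23], ref, ref)

    def test_tag_in_neither_is_not_specific(self):
        assert not m.is_specific("A" * 21, "C" * 100, "G" * 100)

    def test_mutated_homolog_window_makes_tag_specific(self, rng):
        target = "".join(rng.choice(list("ACGT"), size=200))
        tag = target[50:71]
        # mutate every candidate homolog window by >= 1 nt: flip every 10th base
        homolog = "".join(
            ("A" if b != "A" else "C") if i % 10 == 0 else b
            for i, b in enumerate(target)
        )
        assert naive_min_mismatch(tag, homolog) >= 1
        assert m.is_specific(tag, target, homolog)
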