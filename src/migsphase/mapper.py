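"""Exact, ungapped placement of tags on references, both strands.

Mapping is perfect-match only: a tag hits the forward strand where it equals
the reference window, and the reverse strand where its reverse complement
does. ``min_mismatch`` additionally gives the minimal Hamming distance to any
same-length window (either strand), which backs the homolog-specificity call:
a tag is target-specific when it occurs exactly in the target but has at
least one mismatch against every window of the homolog.

References may carry IUPAC ambiguity codes; an ambiguous reference base never
matches any read base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import Library, SequenceTag, revcomp

BOTH_STRANDS = ("+", "-")


@dataclass(frozen=True)
class MatchHit:
    """One perfect-match placement of a tag on a reference.

    ``start`` is the 0-based coordinate of the matched window on the
    reference forward strand; strand "-" means the tag equals the reverse
    complement of that window.
    """

    tag: SequenceTag
    ref_name: str
    start: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in BOTH_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.tag.length

    @property
    def count(self) -> int:
        return self.tag.count

    @property
    def end(self) -> int:
        return self.start + self.length


def _as_tag(tag: SequenceTag | str) -> SequenceTag:
    return tag if isinstance(tag, SequenceTag) else SequenceTag(tag)


def _find_all(needle: str, hay: str) -> list[int]:
    out: list[int] = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_occurrences(
    tag: SequenceTag | str,
    reference: str,
    ref_name: str = "ref",
    strands: Sequence[str] = BOTH_STRANDS,
) -> list[MatchHit]:
    """All exact placements of a tag on a reference, sorted by (start, strand)."""
    tag = _as_tag(tag)
    hits: list[MatchHit] = []
    if tag.length > len(reference):
        return hits
    if "+" in strands:
        for start in _find_all(tag.sequence, reference):
            hits.append(MatchHit(tag, ref_name, start, "+"))
    if "-" in strands:
        for start in _find_all(revcomp(tag.sequence), reference):
            hits.append(MatchHit(tag, ref_name, start, "-"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _window_index(reference: str, length: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - length + 1):
        index.setdefault(reference[i : i + length], []).append(i)
    return index


def map_library(
    library: Library,
    reference: str,
    ref_name: str = "ref",
    length_filter: Iterable[int] | None = None,
    strands: Sequence[str] = BOTH_STRANDS,
) -> list[MatchHit]:
    """Perfect-match placements of every (length-filtered) tag on a reference.

    A tag matching k windows yields k hits, each carrying the tag's full read
    count. Results are sorted by (start, strand, sequence).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    keep = set(length_filter) if length_filter is not None else None
    lengths = sorted(
        {t.length for t in library.tags if (keep is None or t.length in keep)}
    )
    hits: list[MatchHit] = []
    for length in lengths:
        if length > len(reference):
            continue
        index = _window_index(reference, length)
        for tag in library.tags:
            if tag.length != length:
                continue
            if "+" in strands:
                for start in index.get(tag.sequence, ()):
                    hits.append(MatchHit(tag, ref_name, start, "+"))
            if "-" in strands:
                for start in index.get(revcomp(tag.sequence), ()):
                    hits.append(MatchHit(tag, ref_name, start, "-"))
    hits.sort(key=lambda h: (h.start, h.strand, h.tag.sequence))
    return hits


_ACGT_CODES = frozenset(b"ACGT")


def _encode(seq: str, mask_ambiguous: bool) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if mask_ambiguous:
        # ambiguity codes -> 0, which equals no read base
        valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        arr[~valid] = 0
    return arr


def min_mismatch(tag: SequenceTag | str, reference: str) -> int | None:
    """Minimal Hamming distance to any same-length window, either strand.

    Returns 0 iff the tag occurs exactly. Returns ``None`` ("no alignment")
    when the tag is longer than the reference; callers treating this as a
    mismatch count should read it as >= 1.
    """
    tag = _as_tag(tag)
    n = len(reference)
    if tag.length > n:
        return None
    ref = _encode(reference, mask_ambiguous=True)
    windows = sliding_window_view(ref, tag.length)
    fwd = _encode(tag.sequence, mask_ambiguous=False)
    rev = _encode(revcomp(tag.sequence), mask_ambiguous=False)
    best_fwd = int((windows != fwd).sum(axis=1).min())
    best_rev = int((windows != rev).sum(axis=1).min())
    return min(best_fwd, best_rev)


def is_specific(
    tag: SequenceTag | str, target_ref: str, homolog_ref: str
) -> bool:
    """True iff the tag occurs exactly in the target but in no homolog window.

    "At least one mismatched nucleotide" to the homolog is operationalized as
    the absence of an exact occurrence on either strand (min_mismatch >= 1).
    """
    tag = _as_tag(tag)
    if not find_occurrences(tag, target_ref):
        return False
    mm = min_mismatch(tag, homolog_ref)
    return mm is None or mm >= 1


def hits_to_bed6(hits: Iterable[MatchHit], path: str | Path) -> None:
    """Hits as BED6: ref, start, end, tag sequence, read count, strand."""
    with open(path, "w") as fh:
        fh.write("#ref\tstart\tend\ttag\tcount\tstrand\t(0-based half-open)\n")
        for h in hits:
            fh.write(
                f"{h.ref_name}\t{h.start}\t{h.end}\t{h.tag.sequence}\t{h.count}\t{h.strand}\n"
            )


def coverage_bedgraph(
    hits: Iterable[MatchHit], strand: str, path: str | Path
) -> None:
    """Per-position 5'-end read abundance for one strand as bedGraph lines."""
    depth: dict[tuple[str, int], int] = {}
    for h in hits:
        if h.strand != strand:
            continue
        key = (h.ref_name, h.start)
        depth[key] = depth.get(key, 0) + h.count
    with open(path, "w") as fh:
        fh.write(f"#bedGraph of read 5'-position abundance, strand {strand}\n")
        for (ref, pos), n in sorted(depth.items()):
            fh.write(f"{ref}\t{pos}\t{pos + 1}\t{n}\n")
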