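"""Processing profiles of small RNAs on a miRNA stem-loop.

Hairpin products are sense to the precursor transcript, so only
forward-strand exact matches count as precursor-derived. Each matched tag
becomes a species with its position and signed 5'-end offsets relative to
the annotated mature and star sequences (negative = shifted toward the
precursor 5' end), which is how shifted dominant products are described.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import Library
from .mapper import _find_all
from .reference import PrecursorAnnotation


@dataclass(frozen=True)
class PrecursorSpecies:
    sequence: str
    start: int
    length: int
    count: int
    offset_vs_mature: int
    offset_vs_star: int
    multimapped: bool = False


@dataclass(frozen=True)
class PrecursorProfile:
    species: tuple[PrecursorSpecies, ...]
    total_matched_reads: int

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)


def precursor_profile(
    library: Library, annotation: PrecursorAnnotation, min_count: int = 1
) -> PrecursorProfile:
    """Species table of tags matching the stem-loop, sorted by abundance.

    Sort order: descending count, then (start, length) ascending, so ranking
    is a deterministic function of the library. ``total_matched_reads``
    counts all matched reads, before the ``min_count`` display threshold.
    A tag with several stem-loop occurrences (pathological) is assigned its
    leftmost start and flagged ``multimapped``.
    """
    species: list[PrecursorSpecies] = []
    total = 0
    for tag in library.tags:
        starts = _find_all(tag.sequence, annotation.stemloop)
        if not starts:
            continue
        total += tag.count
        if tag.count < min_count:
            continue
        start = starts[0]
        species.append(
            PrecursorSpecies(
                sequence=tag.sequence,
                start=start,
                length=tag.length,
                count=tag.count,
                offset_vs_mature=start - annotation.mature.start,
                offset_vs_star=start - annotation.star.start,
                multimapped=len(starts) > 1,
            )
        )
    species.sort(key=lambda s: (-s.count, s.start, s.length))
    return PrecursorProfile(species=tuple(species), total_matched_reads=total)


def dominant_species(
    profile: PrecursorProfile, k: int
) -> tuple[list[PrecursorSpecies], bool]:
    """Top-k species by read count; second value flags a shortfall (< k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top = list(profile.species[:k])
    return top, len(top) < k


def processing_fidelity(
    profile: PrecursorProfile, annotation: PrecursorAnnotation
) -> float | None:
    """Fraction of matched reads that are exactly the mature or star sequence.

    Returns ``None`` (undefined) when no reads matched the stem-loop. A
    faithfully diced precursor gives 1.0; shifted dominant species push the
    value toward 0.
    """
    if profile.total_matched_reads == 0:
        return None
    canonical = {annotation.mature_sequence, annotation.star_sequence}
    exact = sum(s.count for s in profile.species if s.sequence in canonical)
    return exact / profile.total_matched_reads


def write_profile_tsv(profile: PrecursorProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#sequence\tstart\tlength\tcount\toffset_vs_mature\toffset_vs_star"
            "\tmultimapped\t(0-based)\n"
        )
        for s in profile.species:
            fh.write(
                f"{s.sequence}\t{s.start}\t{s.length}\t{s.count}"
                f"\t{s.offset_vs_mature}\t{s.offset_vs_star}"
                f"\t{str(s.multimapped).lower()}\n"
            )
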