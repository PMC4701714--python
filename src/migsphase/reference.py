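"""Reference models: the MIGS cassette, miRNA precursor, and region lookups.

Coordinates are 0-based, half-open, on the forward (transcript) strand
throughout. The cassette is an ordered concatenation of named elements
(promoter, leader, miRNA target site, target-gene fragment, terminator);
the predicted cleavage coordinate is the first nucleotide of the 3'
cleavage fragment, i.e. the start of phase 1 of the phasiRNA register.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import normalize_reference

#: 22-nt miR173 target site used in MIGS constructs (shared 5' extension of
#: the cassette-building forward primers).
MIR173_TARGET_SITE = "GTGATTTTTCTCTACAAGCGAA"


@dataclass(frozen=True)
class Region:
    """A named half-open interval [start, end) on a reference."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region {self.name}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, coord: int) -> bool:
        return self.start <= coord < self.end


@dataclass(frozen=True)
class CassetteSpec:
    """The MIGS transcript model.

    ``cleavage_coord`` is the 0-based coordinate of the first nucleotide of
    the 3' fragment released by miRNA-guided cleavage (cut between the
    target nucleotides pairing miRNA positions 10 and 11).
    """

    sequence: str
    regions: tuple[Region, ...]
    target_site: Region
    cleavage_coord: int
    name: str = "cassette"

    def __post_init__(self) -> None:
        prev_end = 0
        for region in self.regions:
            if region.start != prev_end:
                raise ValueError(
                    f"regions must tile the cassette; gap/overlap before {region.name}"
                )
            prev_end = region.end
        if prev_end != len(self.sequence):
            raise ValueError("regions do not cover the full cassette sequence")
        if not (self.target_site.start < self.cleavage_coord < self.target_site.end):
            raise ValueError(
                f"cleavage coordinate {self.cleavage_coord} must fall strictly "
                f"inside the target site [{self.target_site.start}, {self.target_site.end})"
            )

    def region_sequence(self, name: str) -> str:
        for region in self.regions:
            if region.name == name:
                return self.sequence[region.start:region.end]
        raise KeyError(f"no region named {name!r}")

    def region_named(self, name: str) -> Region:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(f"no region named {name!r}")


@dataclass(frozen=True)
class PrecursorAnnotation:
    """A miRNA stem-loop with its annotated mature and star intervals."""

    stemloop: str
    mature: Region
    star: Region

    def __post_init__(self) -> None:
        n = len(self.stemloop)
        for region in (self.mature, self.star):
            if region.end > n:
                raise ValueError(f"{region.name} extends past the stem-loop ({n} nt)")
        if max(self.mature.start, self.star.start) < min(self.mature.end, self.star.end):
            raise ValueError("mature and star regions must not overlap")

    @property
    def mature_sequence(self) -> str:
        return self.stemloop[self.mature.start:self.mature.end]

    @property
    def star_sequence(self) -> str:
        return self.stemloop[self.star.start:self.star.end]


def predicted_cleavage_coord(target_site: Region, mirna_length: int) -> int:
    """Predicted slicing coordinate for a miRNA bound end-to-end to its site.

    RISC cuts the target between the nucleotides pairing miRNA positions 10
    and 11 (counted from the miRNA 5' end); with antiparallel end-to-end
    pairing the first nucleotide of the 3' fragment sits at
    ``target_site.start + (mirna_length - 10)``.
    """
    if target_site.length != mirna_length:
        raise ValueError(
            f"target site length {target_site.length} != miRNA length "
            f"{mirna_length}; supply an explicit cleavage coordinate override"
        )
    return target_site.start + (mirna_length - 10)


def assemble_cassette(
    elements: Sequence[tuple[str, str]],
    target_site_name: str = "miR173ts",
    mirna_length: int | None = None,
    cleavage_override: int | None = None,
    name: str = "cassette",
) -> CassetteSpec:
    """Concatenate ordered named elements into a cassette model.

    The element named ``target_site_name`` (present exactly once) becomes the
    miRNA target site; the cleavage coordinate is derived from the 10/11 rule
    unless ``cleavage_override`` (an absolute cassette coordinate) is given.
    """
    names = [n for n, _ in elements]
    if names.count(target_site_name) != 1:
        raise ValueError(
            f"target-site element {target_site_name!r} must appear exactly once "
            f"(found {names.count(target_site_name)})"
        )
    regions: list[Region] = []
    parts: list[str] = []
    pos = 0
    for elem_name, raw in elements:
        seq = normalize_reference(raw)
        if not seq:
            raise ValueError(f"element {elem_name!r} has empty sequence")
        regions.append(Region(elem_name, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    target = next(r for r in regions if r.name == target_site_name)
    if cleavage_override is not None:
        cleavage = cleavage_override
    else:
        cleavage = predicted_cleavage_coord(
            target, mirna_length if mirna_length is not None else target.length
        )
    return CassetteSpec(
        sequence="".join(parts),
        regions=tuple(regions),
        target_site=target,
        cleavage_coord=cleavage,
        name=name,
    )


def region_of(coord: int, cassette: CassetteSpec) -> str:
    """Name of the unique region containing a cassette coordinate."""
    if not 0 <= coord < len(cassette.sequence):
        raise IndexError(
            f"coordinate {coord} outside cassette [0, {len(cassette.sequence)})"
        )
    starts = [r.start for r in cassette.regions]
    idx = bisect_right(starts, coord) - 1
    return cassette.regions[idx].name


def write_cassette_fasta(cassette: CassetteSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cassette.name}\n{cassette.sequence}\n")


def write_regions_bed(cassette: CassetteSpec, path: str | Path) -> None:
    """Regions as BED (0-based half-open), one line per element."""
    with open(path, "w") as fh:
        for region in cassette.regions:
            fh.write(f"{cassette.name}\t{region.start}\t{region.end}\t{region.name}\n")
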