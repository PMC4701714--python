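"""Region-wise tallies, transitivity summaries, and homolog-specific catalogs.

These summaries answer three questions about a mapped library: where on the
cassette do the siRNAs come from (region tallies), does silencing spread
directionally along an endogenous transcript (upstream vs downstream of the
trigger fragment), and which siRNAs can only derive from one member of a
homologous gene pair (the specificity catalog).

Hits are assigned to regions and to the upstream/within/downstream classes
by their 5'-start coordinate on the reference forward strand, so every hit
falls in exactly one class and tallies partition the hit set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import Library
from .mapper import MatchHit, find_occurrences, is_specific
from .reference import CassetteSpec, region_of


@dataclass(frozen=True)
class RegionTally:
    name: str
    reads: int
    species: int
    species_over_threshold: int


def coverage_by_region(
    hits: Sequence[MatchHit],
    cassette: CassetteSpec,
    threshold: int = 5,
    strict: bool = True,
) -> list[RegionTally]:
    """Per-region read/species tallies over cassette hits.

    ``species_over_threshold`` counts tags with reads > threshold when
    ``strict`` (the default reading of "more than 5 read counts"), or
    >= threshold otherwise; the cutoff is presentational and configurable.
    """
    reads: dict[str, int] = {r.name: 0 for r in cassette.regions}
    species: dict[str, set[str]] = {r.name: set() for r in cassette.regions}
    over: dict[str, set[str]] = {r.name: set() for r in cassette.regions}
    for hit in hits:
        region = region_of(hit.start, cassette)
        reads[region] += hit.count
        species[region].add(hit.tag.sequence)
        passes = hit.count > threshold if strict else hit.count >= threshold
        if passes:
            over[region].add(hit.tag.sequence)
    return [
        RegionTally(
            name=r.name,
            reads=reads[r.name],
            species=len(species[r.name]),
            species_over_threshold=len(over[r.name]),
        )
        for r in cassette.regions
    ]


@dataclass(frozen=True)
class TransitivitySummary:
    upstream_reads: int
    within_reads: int
    downstream_reads: int
    upstream_species: int
    within_species: int
    downstream_species: int
    verdict: str  # "5'->3'", "3'->5'", or "not directional"


def transitivity_summary(
    hits: Sequence[MatchHit],
    anchor_interval: tuple[int, int],
    factor: float = 10.0,
) -> TransitivitySummary:
    """Read/species totals 5' of, within, and 3' of an anchor interval.

    The anchor is the cleavage site (zero-length interval) or the trigger
    fragment's span on an endogenous gene. Verdict "5'->3'" requires
    downstream reads to exceed upstream reads by ``factor``; the mirror case
    gives "3'->5'"; anything else is "not directional".
    """
    s, e = anchor_interval
    if s > e:
        raise ValueError(f"invalid anchor interval {anchor_interval}")
    reads = [0, 0, 0]
    species: list[set[str]] = [set(), set(), set()]
    for hit in hits:
        if hit.start < s:
            k = 0
        elif hit.start < e:
            k = 1
        else:
            k = 2
        reads[k] += hit.count
        species[k].add(hit.tag.sequence)
    up, within, down = reads
    if down > 0 and down > factor * up:
        verdict = "5'->3'"
    elif up > 0 and up > factor * down:
        verdict = "3'->5'"
    else:
        verdict = "not directional"
    return TransitivitySummary(
        upstream_reads=up,
        within_reads=within,
        downstream_reads=down,
        upstream_species=len(species[0]),
        within_species=len(species[1]),
        downstream_species=len(species[2]),
        verdict=verdict,
    )


@dataclass(frozen=True)
class CatalogEntry:
    sequence: str
    count: int
    hits: tuple[MatchHit, ...]  # placements on the target gene


@dataclass(frozen=True)
class SpecificCatalog:
    entries: tuple[CatalogEntry, ...]
    n_species: int
    max_count: int

    @property
    def sequences(self) -> set[str]:
        return {e.sequence for e in self.entries}


def specific_sirna_catalog(
    library: Library,
    target_gene: str,
    homolog: str,
    length: int = 21,
    target_name: str = "target",
) -> SpecificCatalog:
    """Catalog of target-gene-specific siRNA species.

    An siRNA species is target-specific when it matches the target gene
    perfectly (either strand) and has at least one mismatch against every
    same-length window of the homolog. Entries are sorted by descending
    count then sequence.
    """
    entries: list[CatalogEntry] = []
    for tag in library.tags:
        if tag.length != length:
            continue
        if not is_specific(tag, target_gene, homolog):
            continue
        hits = tuple(find_occurrences(tag, target_gene, ref_name=target_name))
        entries.append(CatalogEntry(sequence=tag.sequence, count=tag.count, hits=hits))
    entries.sort(key=lambda e: (-e.count, e.sequence))
    return SpecificCatalog(
        entries=tuple(entries),
        n_species=len(entries),
        max_count=max((e.count for e in entries), default=0),
    )


def write_region_tallies_tsv(tallies: Iterable[RegionTally], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#region\treads\tspecies\tspecies_over_threshold\n")
        for t in tallies:
            fh.write(f"{t.name}\t{t.reads}\t{t.species}\t{t.species_over_threshold}\n")


def write_catalog_tsv(catalog: SpecificCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sequence\tcount\tn_placements\tfirst_start\tfirst_strand\n")
        for e in catalog.entries:
            first = e.hits[0] if e.hits else None
            start = first.start if first else -1
            strand = first.strand if first else "."
            fh.write(f"{e.sequence}\t{e.count}\t{len(e.hits)}\t{start}\t{strand}\n")


def write_transitivity_tsv(
    summaries: dict[str, TransitivitySummary], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#reference\tupstream_reads\twithin_reads\tdownstream_reads"
            "\tupstream_species\twithin_species\tdownstream_species\tverdict\n"
        )
        for name, t in sorted(summaries.items()):
            fh.write(
                f"{name}\t{t.upstream_reads}\t{t.within_reads}\t{t.downstream_reads}"
                f"\t{t.upstream_species}\t{t.within_species}\t{t.downstream_species}"
                f"\t{t.verdict}\n"
            )
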