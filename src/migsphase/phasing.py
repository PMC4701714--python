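"""Phase-register analysis of 21-nt siRNA hits downstream of a cleavage site.

miRNA-guided cleavage defines a register: successive Dicer cuts release
21-nt duplexes head-to-tail from the first nucleotide of the 3' cleavage
fragment (coordinate ``c``). Each duplex spans a 21-nt *unit* anchored at its
sense-strand start ``a``; the antisense strand of a duplex with a 2-nt 3'
overhang starts at ``a - 2`` on the reference, so antisense hits are shifted
by +overhang before phase assignment and the two strands of one duplex share
a phase.

phase = ((a - c) mod period) + 1   (phase 1 = in-phase with the register)
cycle = floor((a - c) / period) + 1 (cycle 1 = first unit downstream of c)

Hits upstream of the cleavage site (cycle <= 0) are excluded from ratios;
non-period-length hits are excluded with a reason code. Both exclusions are
reported so read totals reconcile.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import RatioResult
from .mapper import MatchHit

EXCLUDE_WRONG_LENGTH = "length!=period"


@dataclass(frozen=True)
class PhasingConfig:
    period: int = 21
    overhang: int = 2
    cleavage_coord: int = 0
    n_cycles_report: int | None = None  # None = until reference end

    def __post_init__(self) -> None:
        if not self.period > self.overhang >= 0:
            raise ValueError(
                f"require period > overhang >= 0, got {self.period}/{self.overhang}"
            )


@dataclass(frozen=True)
class PhasedHit:
    hit: MatchHit
    anchor: int
    phase: int
    cycle: int

    @property
    def count(self) -> int:
        return self.hit.count


def phase_assign(hit: MatchHit, config: PhasingConfig) -> PhasedHit:
    """Anchor, phase (1..period) and processing cycle for one hit."""
    if hit.length != config.period:
        raise ValueError(
            f"hit length {hit.length} != period {config.period}; "
            f"exclude with reason {EXCLUDE_WRONG_LENGTH!r}"
        )
    anchor = hit.start if hit.strand == "+" else hit.start + config.overhang
    delta = anchor - config.cleavage_coord
    phase = delta % config.period + 1
    cycle = delta // config.period + 1
    return PhasedHit(hit=hit, anchor=anchor, phase=phase, cycle=cycle)


def assign_phases(
    hits: Iterable[MatchHit], config: PhasingConfig
) -> tuple[list[PhasedHit], list[tuple[MatchHit, str]]]:
    """Phase all period-length hits; return (phased, excluded-with-reason)."""
    phased: list[PhasedHit] = []
    excluded: list[tuple[MatchHit, str]] = []
    for hit in hits:
        if hit.length != config.period:
            excluded.append((hit, EXCLUDE_WRONG_LENGTH))
        else:
            phased.append(phase_assign(hit, config))
    return phased, excluded


@dataclass(frozen=True)
class DuplexUnit:
    """Sense/antisense reads consolidated at one duplex anchor."""

    anchor: int
    phase: int
    cycle: int
    sense_reads: int
    antisense_reads: int

    @property
    def total_reads(self) -> int:
        return self.sense_reads + self.antisense_reads


def consolidate_duplexes(phased_hits: Iterable[PhasedHit]) -> list[DuplexUnit]:
    """Merge hits sharing a duplex anchor into one small-RNA unit.

    Paired sense and antisense reads with the 2-nt 3' overhang geometry land
    on the same anchor and merge; a strand without a partner yields a unit
    with 0 reads on the missing strand.
    """
    sense: Counter[int] = Counter()
    anti: Counter[int] = Counter()
    meta: dict[int, tuple[int, int]] = {}
    for ph in phased_hits:
        meta[ph.anchor] = (ph.phase, ph.cycle)
        if ph.hit.strand == "+":
            sense[ph.anchor] += ph.count
        else:
            anti[ph.anchor] += ph.count
    units = [
        DuplexUnit(
            anchor=a,
            phase=meta[a][0],
            cycle=meta[a][1],
            sense_reads=sense.get(a, 0),
            antisense_reads=anti.get(a, 0),
        )
        for a in sorted(meta)
    ]
    return units


@dataclass(frozen=True)
class CycleTally:
    in_reads: int
    out_reads: int


@dataclass(frozen=True)
class PhaseReport:
    """Per-phase and per-cycle tallies downstream of the cleavage site."""

    period: int
    per_phase_reads: tuple[int, ...]
    per_cycle: dict[int, CycleTally]
    in_reads: int
    out_reads: int
    in_species: int
    out_species: int
    upstream_reads: int
    excluded_reads: int

    @property
    def ratio(self) -> RatioResult:
        """In-phase : out-of-phase read ratio (flagged if degenerate)."""
        return RatioResult(numerator=self.in_reads, denominator=self.out_reads)

    @property
    def species_ratio(self) -> RatioResult:
        return RatioResult(numerator=self.in_species, denominator=self.out_species)

    @property
    def in_fraction(self) -> float | None:
        total = self.in_reads + self.out_reads
        return None if total == 0 else self.in_reads / total

    @property
    def occupancy(self) -> set[int]:
        """Set of phases (1..period) populated by at least one read."""
        return {p + 1 for p, n in enumerate(self.per_phase_reads) if n > 0}

    def populated_inphase_cycles(self, cycle_range: tuple[int, int]) -> int:
        """Number of cycles in [lo, hi] whose phase-1 position holds >= 1 read."""
        lo, hi = cycle_range
        return sum(
            1
            for k, tally in self.per_cycle.items()
            if lo <= k <= hi and tally.in_reads > 0
        )


def phase_report(
    phased_hits: Sequence[PhasedHit],
    config: PhasingConfig,
    cycle_range: tuple[int, int] | None = None,
    excluded_reads: int = 0,
) -> PhaseReport:
    """Tally phased hits downstream of the cleavage site.

    Per-phase tallies cover all downstream cycles; the in/out ratio is
    computed over ``cycle_range`` (default: cycle 1 to the reference end).
    Upstream (cycle <= 0) reads are counted separately and excluded.
    """
    per_phase = [0] * config.period
    per_cycle_in: Counter[int] = Counter()
    per_cycle_out: Counter[int] = Counter()
    upstream = 0
    in_reads = out_reads = 0
    in_seqs: set[str] = set()
    out_seqs: set[str] = set()
    for ph in phased_hits:
        if ph.cycle <= 0:
            upstream += ph.count
            continue
        per_phase[ph.phase - 1] += ph.count
        if ph.phase == 1:
            per_cycle_in[ph.cycle] += ph.count
        else:
            per_cycle_out[ph.cycle] += ph.count
        if cycle_range is not None and not (cycle_range[0] <= ph.cycle <= cycle_range[1]):
            continue
        if ph.phase == 1:
            in_reads += ph.count
            in_seqs.add(ph.hit.tag.sequence)
        else:
            out_reads += ph.count
            out_seqs.add(ph.hit.tag.sequence)
    cycles = sorted(set(per_cycle_in) | set(per_cycle_out))
    per_cycle = {
        k: CycleTally(per_cycle_in.get(k, 0), per_cycle_out.get(k, 0)) for k in cycles
    }
    return PhaseReport(
        period=config.period,
        per_phase_reads=tuple(per_phase),
        per_cycle=per_cycle,
        in_reads=in_reads,
        out_reads=out_reads,
        in_species=len(in_seqs),
        out_species=len(out_seqs),
        upstream_reads=upstream,
        excluded_reads=excluded_reads,
    )


def phase_occupancy(phased_hits: Iterable[PhasedHit]) -> set[int]:
    """Phases (1..period) populated by at least one downstream read."""
    return {ph.phase for ph in phased_hits if ph.cycle >= 1}


def write_phase_table(
    phased_hits: Iterable[PhasedHit], path: str | Path
) -> None:
    """Phase assignments as TSV (anchor, phase, cycle, strand, reads, tag)."""
    with open(path, "w") as fh:
        fh.write("#anchor\tphase\tcycle\tstrand\treads\ttag\t(0-based)\n")
        for ph in sorted(
            phased_hits, key=lambda p: (p.anchor, p.hit.strand, p.hit.tag.sequence)
        ):
            fh.write(
                f"{ph.anchor}\t{ph.phase}\t{ph.cycle}\t{ph.hit.strand}"
                f"\t{ph.count}\t{ph.hit.tag.sequence}\n"
            )


def write_cycle_summary(report: PhaseReport, path: str | Path) -> None:
    """Per-cycle summary TSV with an ``inphase_populated`` marker column."""
    with open(path, "w") as fh:
        fh.write("#cycle\tin_reads\tout_reads\tinphase_populated\n")
        for k, tally in sorted(report.per_cycle.items()):
            fh.write(
                f"{k}\t{tally.in_reads}\t{tally.out_reads}"
                f"\t{str(tally.in_reads > 0).lower()}\n"
            )
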