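"""Synthetic small-RNA libraries with per-read ground truth.

The generator emulates the read classes a MIGS experiment produces:

* phased 21-nt duplexes released head-to-tail downstream of the miRNA
  cleavage site, with Poisson read counts decaying geometrically per cycle
  and a cumulative +/-1-nt register slip at cycle boundaries (misprocessing
  in one cycle shifts every later cycle);
* a configurable share of the same duplex positions emitted as 22-mers;
* unphased secondary (transitive) siRNAs at uniform positions strictly 3'
  of the trigger fragment on each endogenous gene, both strands;
* precursor reads drawn from a configurable stem-loop processing profile
  (so a shifted species can dominate while the annotated mature is rare);
* uniform sense-strand background degradation reads on the long transcripts.

Every read carries an origin label, so analyses can be checked against the
generating truth (parameter recovery, specificity soundness, conservation).
Identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io import Library, revcomp
from .reference import (
    MIR173_TARGET_SITE,
    CassetteSpec,
    PrecursorAnnotation,
    Region,
    assemble_cassette,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ProfileEntry:
    """One precursor species: anchor ('mature'|'star'), 5' offset, length, share."""

    anchor: str
    offset: int
    length: int
    proportion: float


#: Default precursor processing profile: the annotated 22-nt mature product is
#: rare, the star is nearly absent, and two species shifted 4 nt toward the
#: precursor 5' end of the star (20- and 21-mers) dominate.
DEFAULT_PRECURSOR_PROFILE: tuple[ProfileEntry, ...] = (
    ProfileEntry("mature", 0, 22, 0.031),
    ProfileEntry("star", 0, 21, 0.001),
    ProfileEntry("star", -4, 20, 0.642),
    ProfileEntry("star", -4, 21, 0.275),
    ProfileEntry("mature", 2, 21, 0.051),
)


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; defaults are the study conditions the analyses assume."""

    seed: int = 0
    n_cycles: int = 25
    duplex_mean: float = 400.0  # mean reads in cycle 1
    decay: float = 0.7  # per-cycle geometric decay of duplex abundance
    slip_prob: float = 0.15  # per-cycle-boundary prob of a +/-1 register slip
    strand_bias: float = 0.5  # fraction of duplex reads from the sense strand
    frac_22nt: float = 0.2  # share of cassette duplex reads emitted as 22-mers
    secondary_rate: float = 2.0  # mean secondary reads per downstream gene position
    background_rate: float = 50.0  # mean degradation reads per long reference
    identity: float = 0.86  # pairwise identity of the simulated homolog pair
    precursor_reads: float = 3000.0  # mean total precursor-derived reads
    precursor_profile: tuple[ProfileEntry, ...] = DEFAULT_PRECURSOR_PROFILE

    def __post_init__(self) -> None:
        for name in ("slip_prob", "strand_bias", "frac_22nt", "decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(f"identity must be in (0, 1], got {self.identity}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        total = sum(e.proportion for e in self.precursor_profile)
        if self.precursor_profile and abs(total - 1.0) > 1e-9:
            raise ValueError(f"precursor profile proportions sum to {total}, not 1")


@dataclass(frozen=True)
class GeneModel:
    """An endogenous gene sequence with the trigger fragment's interval."""

    sequence: str
    fragment: tuple[int, int]


@dataclass
class SimulationTruth:
    """Ground truth: read counts per (sequence, origin label), plus the
    realized register offset at every processing cycle and the parameters."""

    params: SimulationParams
    offsets_per_cycle: list[int]
    records: dict[tuple[str, str], int]

    @property
    def total_reads(self) -> int:
        return sum(self.records.values())

    def label_totals(self) -> Counter[str]:
        out: Counter[str] = Counter()
        for (_, label), n in self.records.items():
            out[label] += n
        return out

    def reads_for(self, *labels: str) -> int:
        keep = set(labels)
        return sum(n for (_, lab), n in self.records.items() if lab in keep)

    def tags_for(self, *labels: str) -> set[str]:
        keep = set(labels)
        return {seq for (seq, lab) in self.records if lab in keep}

    def counts_for(self, *labels: str) -> Counter[str]:
        keep = set(labels)
        out: Counter[str] = Counter()
        for (seq, lab), n in self.records.items():
            if lab in keep:
                out[seq] += n
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#sequence\tlabel\treads\n")
            for (seq, lab), n in sorted(self.records.items()):
                fh.write(f"{seq}\t{lab}\t{n}\n")

    def manifest(self) -> dict:
        params = asdict(self.params)
        params["precursor_profile"] = [asdict(e) for e in self.params.precursor_profile]
        return {"params": params, "offsets_per_cycle": self.offsets_per_cycle}


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_sequence(
    rng: np.random.Generator, sequence: str, rate: float
) -> tuple[str, float]:
    """I.i.d. substitutions at the given rate; returns (mutant, realized identity)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n_mut = int(hit.sum())
    if n_mut:
        # substitute with a uniformly chosen *different* base
        for i in np.flatnonzero(hit):
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), 1.0 - n_mut / len(arr)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    realized_identity: float


def simulate_homolog_pair(
    seed: int | np.random.Generator, length: int, identity: float = 0.86
) -> HomologPair:
    """A random gene and a homolog diverged by i.i.d. substitutions."""
    if length < 100:
        raise ValueError("length must be >= 100")
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_a = random_sequence(rng, length)
    gene_b, realized = mutate_sequence(rng, gene_a, 1.0 - identity)
    return HomologPair(gene_a=gene_a, gene_b=gene_b, realized_identity=realized)


@dataclass(frozen=True)
class Scenario:
    """A full simulated study: cassette, homolog pair, and stem-loop."""

    cassette: CassetteSpec
    genes: dict[str, GeneModel]
    precursor: PrecursorAnnotation
    realized_identity: float


def default_scenario(
    seed: int,
    identity: float = 0.86,
    gene_length: int = 1800,
    fragment_interval: tuple[int, int] = (800, 1263),
    promoter_length: int = 200,
    leader_length: int = 70,
    terminator_length: int = 200,
    stemloop_length: int = 120,
) -> Scenario:
    """Build the default simulated references.

    Gene A is random; the 463-nt trigger fragment is an exact subsequence of
    gene A (as when the fragment is amplified from the target gene's cDNA);
    gene B is gene A diverged to the requested identity. The cassette is
    promoter / viral leader / 22-nt miR173 target site / fragment /
    terminator. The stem-loop is random with non-overlapping mature (22 nt)
    and star (21 nt) annotations placed so the default shifted species fit.
    """
    rng = np.random.default_rng(seed)
    pair = simulate_homolog_pair(rng, gene_length, identity)
    s, e = fragment_interval
    if not 0 <= s < e <= gene_length:
        raise ValueError(f"fragment interval {fragment_interval} outside gene")
    fragment = pair.gene_a[s:e]
    cassette = assemble_cassette(
        [
            ("promoter_35S", random_sequence(rng, promoter_length)),
            ("TL", random_sequence(rng, leader_length)),
            ("miR173ts", MIR173_TARGET_SITE),
            ("target_fragment", fragment),
            ("terminator_35S", random_sequence(rng, terminator_length)),
        ]
    )
    stemloop = random_sequence(rng, stemloop_length)
    precursor = PrecursorAnnotation(
        stemloop=stemloop,
        mature=Region("mature", 16, 38),
        star=Region("star", 62, 83),
    )
    genes = {
        "geneA": GeneModel(pair.gene_a, fragment_interval),
        "geneB": GeneModel(pair.gene_b, fragment_interval),
    }
    return Scenario(
        cassette=cassette,
        genes=genes,
        precursor=precursor,
        realized_identity=pair.realized_identity,
    )


def _fragment_matches(cassette: CassetteSpec, gene: GeneModel) -> bool:
    frag = cassette.region_sequence("target_fragment")
    s, e = gene.fragment
    window = gene.sequence[s:e]
    if len(window) != len(frag) or not window:
        return False
    same = sum(a == b for a, b in zip(frag, window))
    return same / len(frag) >= 0.5


def simulate_library(
    cassette: CassetteSpec,
    genes: Mapping[str, GeneModel],
    params: SimulationParams,
    precursor: PrecursorAnnotation | None = None,
    name: str | None = None,
) -> tuple[Library, SimulationTruth]:
    """Draw one library and its ground truth from the generative model."""
    for gname, gene in genes.items():
        if not _fragment_matches(cassette, gene):
            raise ValueError(
                f"gene {gname!r} does not carry the cassette's trigger fragment "
                f"at interval {gene.fragment}"
            )
    rng = np.random.default_rng(params.seed)
    records: Counter[tuple[str, str]] = Counter()
    seq = cassette.sequence
    c = cassette.cleavage_coord
    period, overhang = 21, 2

    # (i)+(ii) phased duplexes on the cassette, 21- and 22-mers
    offset = 0
    offsets: list[int] = []
    for k in range(1, params.n_cycles + 1):
        if k > 1 and rng.random() < params.slip_prob:
            offset += int(rng.choice((-1, 1)))
        offsets.append(offset)
        anchor = c + (k - 1) * period + offset
        n = int(rng.poisson(params.duplex_mean * params.decay ** (k - 1)))
        if n == 0:
            continue
        if anchor - overhang < 0 or anchor + period + 1 > len(seq):
            continue  # duplex (incl. 22-mer and antisense window) must fit
        label = "phased_primary" if offset == 0 else "slipped"
        n22 = int(rng.binomial(n, params.frac_22nt))
        for n_len, length in ((n - n22, period), (n22, period + 1)):
            if n_len == 0:
                continue
            n_sense = int(rng.binomial(n_len, params.strand_bias))
            sense = seq[anchor : anchor + length]
            anti = revcomp(seq[anchor - overhang : anchor - overhang + length])
            if n_sense:
                records[(sense, label)] += n_sense
            if n_len - n_sense:
                records[(anti, label)] += n_len - n_sense

    # (iii) unphased secondary siRNAs strictly 3' of the fragment in each gene
    for gname in sorted(genes):
        gene = genes[gname]
        lo = gene.fragment[1]
        hi = len(gene.sequence) - period
        if hi < lo:
            continue
        n = int(rng.poisson(params.secondary_rate * (hi - lo + 1)))
        if n == 0:
            continue
        positions = rng.integers(lo, hi + 1, size=n)
        sense_mask = rng.random(n) < 0.5
        label = f"secondary:{gname}"
        for pos, is_sense in zip(positions, sense_mask):
            window = gene.sequence[pos : pos + period]
            records[(window if is_sense else revcomp(window), label)] += 1

    # (iv) precursor reads per the configured processing profile
    if precursor is not None and params.precursor_profile:
        n = int(rng.poisson(params.precursor_reads))
        props = [e.proportion for e in params.precursor_profile]
        draws = rng.multinomial(n, props)
        for entry, cnt in zip(params.precursor_profile, draws):
            cnt = int(cnt)
            if cnt == 0:
                continue
            base = precursor.mature if entry.anchor == "mature" else precursor.star
            start = base.start + entry.offset
            if start < 0 or start + entry.length > len(precursor.stemloop):
                raise ValueError(
                    f"precursor profile entry {entry} falls outside the stem-loop"
                )
            read = precursor.stemloop[start : start + entry.length]
            records[(read, f"precursor:{entry.anchor}{entry.offset:+d}.{entry.length}")] += cnt

    # (v) uniform sense-strand degradation background on the long transcripts
    refs = {"cassette": seq}
    refs.update({gname: genes[gname].sequence for gname in sorted(genes)})
    for rname, rseq in refs.items():
        n = int(rng.poisson(params.background_rate))
        if n == 0:
            continue
        lengths = rng.integers(18, 27, size=n)
        for length in lengths:
            pos = int(rng.integers(0, len(rseq) - int(length) + 1))
            records[(rseq[pos : pos + int(length)], f"background:{rname}")] += 1

    counts: Counter[str] = Counter()
    for (read_seq, _), n in records.items():
        counts[read_seq] += n
    library = Library.from_counts(counts, name=name or f"sim_seed{params.seed}")
    truth = SimulationTruth(
        params=params, offsets_per_cycle=offsets, records=dict(records)
    )
    return library, truth


def write_manifest(truth: SimulationTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
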