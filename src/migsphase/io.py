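"""Small-RNA library ingestion, collapsing, and summary statistics.

A sequencing library is held as a set of unique *tags* (collapsed read
sequences), each carrying the number of redundant reads that produced it.
All sequences are normalized to uppercase DNA (U -> T) at ingestion, so
downstream matching is DNA-vs-DNA against GenBank-style references.

Supported inputs: plain FASTA (one read per record), 4-line FASTQ, and
"collapsed FASTA" where the read count is encoded in the header, either as
``>t{i}_x{count}`` or ``>{id} count={n}``.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_COLLAPSED_X = re.compile(r"_x(\d+)$")
_COLLAPSED_KV = re.compile(r"\bcount=(\d+)\b")


def normalize_sequence(raw: str, context: str = "") -> str:
    """Uppercase a read sequence and convert RNA U to DNA T.

    Raises ``ValueError`` if any character outside A/C/G/T remains, naming
    the offending sequence (ambiguity codes are not accepted in reads).
    """
    seq = str(raw).translate(_RNA_TO_DNA).upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        where = f" in {context}" if context else ""
        raise ValueError(
            f"non-ACGTU character(s) {sorted(bad)}{where}: sequence {seq!r}"
        )
    return seq


def normalize_reference(raw: str) -> str:
    """Uppercase a reference sequence, U -> T; IUPAC ambiguity codes are kept.

    Ambiguous reference positions never match any read base downstream.
    """
    return str(raw).translate(_RNA_TO_DNA).upper()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceTag:
    """A collapsed unique small-RNA sequence with its redundant read count."""

    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"tag count must be >= 1, got {self.count}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"tag contains non-ACGT characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Library:
    """A collapsed small-RNA library: distinct tags plus the read total."""

    tags: tuple[SequenceTag, ...]
    total_reads: int
    name: str = "library"

    def __post_init__(self) -> None:
        seqs = [t.sequence for t in self.tags]
        if len(seqs) != len(set(seqs)):
            raise ValueError("library tags must have distinct sequences")
        total = sum(t.count for t in self.tags)
        if total != self.total_reads:
            raise ValueError(
                f"total_reads {self.total_reads} != sum of tag counts {total}"
            )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], name: str = "library") -> "Library":
        tags = tuple(
            SequenceTag(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        return cls(tags=tags, total_reads=sum(counts.values()), name=name)

    @property
    def counts(self) -> dict[str, int]:
        return {t.sequence: t.count for t in self.tags}

    @property
    def n_species(self) -> int:
        return len(self.tags)

    def filter_length(self, lengths: Iterable[int]) -> "Library":
        keep = set(lengths)
        tags = tuple(t for t in self.tags if t.length in keep)
        return Library(tags=tags, total_reads=sum(t.count for t in tags), name=self.name)


def _collapsed_count(header: str) -> int | None:
    m = _COLLAPSED_X.search(header.split()[0]) if header else None
    if m:
        return int(m.group(1))
    m = _COLLAPSED_KV.search(header)
    if m:
        return int(m.group(1))
    return None


def read_library(path: str | Path, format: str = "auto", name: str | None = None) -> Library:
    """Read and collapse a small-RNA library from FASTA/FASTQ/collapsed FASTA.

    Identical sequences are merged into one tag whose count is the number of
    occurrences (or the sum of header-encoded counts for collapsed FASTA).
    """
    path = Path(path)
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    if fmt not in {"fasta", "fastq", "collapsed_fasta"}:
        raise ValueError(f"unknown library format {fmt!r}")

    counts: Counter[str] = Counter()
    parser = SeqIO.parse(str(path), "fastq" if fmt == "fastq" else "fasta")
    record_no = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            lines_per = 4 if fmt == "fastq" else 2
            raise ValueError(
                f"{path}: malformed {fmt} record #{record_no + 1} "
                f"(near line {record_no * lines_per + 1}): {exc}"
            ) from exc
        record_no += 1
        seq = normalize_sequence(
            str(record.seq), context=f"{path} record {record.id or record_no}"
        )
        if fmt == "collapsed_fasta":
            n = _collapsed_count(record.description or record.id)
            if n is None:
                raise ValueError(
                    f"{path}: record {record.id!r} lacks a collapsed-count header "
                    "(expected '_x<count>' or 'count=<n>')"
                )
            counts[seq] += n
        else:
            counts[seq] += 1
    return Library.from_counts(counts, name=name or path.stem)


def write_collapsed(library: Library, path: str | Path) -> None:
    """Write a library in the ``>t{i}_x{count}`` collapsed-FASTA dialect.

    Tags are emitted by descending count then sequence, so output is a
    deterministic function of the library contents.
    """
    ordered = sorted(library.tags, key=lambda t: (-t.count, t.sequence))
    with open(path, "w") as fh:
        for i, tag in enumerate(ordered, start=1):
            fh.write(f">t{i}_x{tag.count}\n{tag.sequence}\n")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Read reference sequences (FASTA) as a name -> sequence mapping."""
    refs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        refs[record.id] = normalize_reference(str(record.seq))
    return refs


def tpm(count: int, total_reads: int) -> float:
    """Transcripts (tags) per million total clean reads of the library."""
    if total_reads <= 0:
        raise ZeroDivisionError("TPM undefined for a library with no reads")
    if not 0 <= count <= total_reads:
        raise ValueError(f"count {count} outside [0, {total_reads}]")
    return count * 1_000_000 / total_reads


def size_histogram(library: Library, min_len: int, max_len: int) -> pd.DataFrame:
    """Per-length read and species counts over a closed length range.

    Returns a DataFrame with columns ``length``, ``read_count``,
    ``species_count``; lengths outside the range are dropped.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    lengths = range(min_len, max_len + 1)
    reads = {n: 0 for n in lengths}
    species = {n: 0 for n in lengths}
    for tag in library.tags:
        if min_len <= tag.length <= max_len:
            reads[tag.length] += tag.count
            species[tag.length] += 1
    return pd.DataFrame(
        {
            "length": list(lengths),
            "read_count": [reads[n] for n in lengths],
            "species_count": [species[n] for n in lengths],
        }
    )


@dataclass(frozen=True)
class RatioResult:
    """A guarded ratio: numerator/denominator read tallies plus flags.

    ``value`` is ``None`` when both tallies are zero ("undefined"),
    ``math.inf`` when only the denominator is zero ("infinite").
    """

    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.numerator == 0 and self.denominator == 0:
            return None
        if self.denominator == 0:
            return math.inf
        return self.numerator / self.denominator

    @property
    def flag(self) -> str | None:
        if self.numerator == 0 and self.denominator == 0:
            return "undefined"
        if self.denominator == 0:
            return "infinite"
        return None


def length_class_ratio(hits, focal_len: int, window: tuple[int, int]) -> RatioResult:
    """Ratio of focal-length reads to other-length reads within a size window.

    ``hits`` are mapper hits restricted to one reference; each distinct tag is
    counted once (multi-mapping placements do not double-count reads).
    """
    lo, hi = window
    if not lo <= focal_len <= hi:
        raise ValueError(f"focal length {focal_len} outside window {window}")
    seen: dict[str, int] = {}
    for hit in hits:
        seen.setdefault(hit.tag.sequence, hit.tag.count)
    focal = sum(
        n for seq, n in seen.items() if len(seq) == focal_len
    )
    other = sum(
        n for seq, n in seen.items() if lo <= len(seq) <= hi and len(seq) != focal_len
    )
    return RatioResult(numerator=focal, denominator=other)


def histogram_to_tsv(histogram: pd.DataFrame, path: str | Path) -> None:
    histogram.to_csv(path, sep="\t", index=False)
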