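"""End-to-end report bundle: run every analysis stage and write its outputs.

``run_report`` reads a library plus references from disk, executes the full
analysis (size histogram, precursor profile, cassette phase report, 21/22-nt
maps, region tallies, per-gene transitivity, homolog-specific catalog) and
writes one TSV per stage plus a ``summary.json`` holding every headline
statistic. ``check_report_consistency`` re-derives the headline numbers from
the stage TSVs and reports any disagreement, so the JSON can be trusted to
be a pure function of the tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as srio
from . import locus, mapper, phasing, precursor
from .reference import CassetteSpec, PrecursorAnnotation, Region, assemble_cassette
from Bio import SeqIO

SIZE_RANGE = (18, 26)
NON21_WINDOW = (20, 24)


@dataclass
class RunConfig:
    library: str
    cassette_elements: str
    outdir: str
    library_format: str = "auto"
    target_site_name: str = "miR173ts"
    cleavage_override: int | None = None
    stemloop: str | None = None
    stemloop_annotation: str | None = None
    genes: str | None = None
    gene_fragments: str | None = None
    target_gene: str | None = None
    homolog_gene: str | None = None
    period: int = 21
    overhang: int = 2
    display_threshold: int = 5
    threshold_strict: bool = True
    directionality_factor: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_cassette(config: RunConfig) -> CassetteSpec:
    elements = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(config.cassette_elements, "fasta")
    ]
    return assemble_cassette(
        elements,
        target_site_name=config.target_site_name,
        cleavage_override=config.cleavage_override,
    )


def load_precursor(config: RunConfig) -> PrecursorAnnotation | None:
    if not config.stemloop or not config.stemloop_annotation:
        return None
    refs = srio.read_reference_fasta(config.stemloop)
    (stemloop,) = refs.values()
    bed = pd.read_csv(
        config.stemloop_annotation,
        sep="\t",
        comment="#",
        header=None,
        names=["ref", "start", "end", "name"],
    )
    rows = {row["name"]: row for _, row in bed.iterrows()}
    if not {"mature", "star"} <= rows.keys():
        raise ValueError("stem-loop annotation must name 'mature' and 'star' intervals")
    return PrecursorAnnotation(
        stemloop=stemloop,
        mature=Region("mature", int(rows["mature"].start), int(rows["mature"].end)),
        star=Region("star", int(rows["star"].start), int(rows["star"].end)),
    )


def locate_fragment(gene: str, fragment: str) -> tuple[int, int]:
    """Interval of the trigger fragment in a gene, exact or best ungapped match."""
    pos = gene.find(fragment)
    if pos != -1:
        return pos, pos + len(fragment)
    from numpy.lib.stride_tricks import sliding_window_view

    ref = np.frombuffer(gene.encode("ascii"), dtype=np.uint8)
    frag = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)
    if len(frag) > len(ref):
        raise ValueError("fragment longer than gene")
    windows = sliding_window_view(ref, len(frag))
    best = int((windows != frag).sum(axis=1).argmin())
    return best, best + len(fragment)


def run_report(config: RunConfig) -> dict:
    """Execute every stage, write the report bundle, return the JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    try:
        summary = _run_stages(config, outdir)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if failed_marker.exists():
        failed_marker.unlink()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _run_stages(config: RunConfig, outdir: Path) -> dict:
    library = srio.read_library(config.library, format=config.library_format)
    cassette = load_cassette(config)
    summary: dict = {
        "config_hash": config.config_hash(),
        "library": library.name,
        "total_reads": library.total_reads,
        "unique_tags": library.n_species,
        "cleavage_coord": cassette.cleavage_coord,
    }

    hist = srio.size_histogram(library, *SIZE_RANGE)
    srio.histogram_to_tsv(hist, outdir / "size_histogram.tsv")
    summary["reads_18_26"] = int(hist["read_count"].sum())

    annotation = load_precursor(config)
    if annotation is not None:
        profile = precursor.precursor_profile(library, annotation)
        precursor.write_profile_tsv(profile, outdir / "precursor_profile.tsv")
        fidelity = precursor.processing_fidelity(profile, annotation)
        mature_reads = sum(
            s.count for s in profile.species if s.sequence == annotation.mature_sequence
        )
        star_reads = sum(
            s.count for s in profile.species if s.sequence == annotation.star_sequence
        )
        top, _ = precursor.dominant_species(profile, 2) if len(profile) else ([], True)
        summary["precursor"] = {
            "matched_reads": profile.total_matched_reads,
            "mature_reads": mature_reads,
            "star_reads": star_reads,
            "top_species_counts": [s.count for s in top],
            "top_species_offsets_vs_star": [s.offset_vs_star for s in top],
            "processing_fidelity": fidelity,
        }

    # cassette maps: 21-nt phasing, 22-nt track, region tallies, size-class ratio
    hits21 = mapper.map_library(
        library, cassette.sequence, ref_name=cassette.name, length_filter={config.period}
    )
    hits22 = mapper.map_library(
        library, cassette.sequence, ref_name=cassette.name, length_filter={config.period + 1}
    )
    mapper.hits_to_bed6(hits21, outdir / "cassette_21nt_hits.bed")
    mapper.hits_to_bed6(hits22, outdir / "cassette_22nt_hits.bed")
    mapper.coverage_bedgraph(hits21, "+", outdir / "cassette_21nt_plus.bedgraph")
    mapper.coverage_bedgraph(hits21, "-", outdir / "cassette_21nt_minus.bedgraph")
    pconfig = phasing.PhasingConfig(
        period=config.period,
        overhang=config.overhang,
        cleavage_coord=cassette.cleavage_coord,
    )
    phased, excluded = phasing.assign_phases(hits21, pconfig)
    report = phasing.phase_report(
        phased, pconfig, excluded_reads=sum(h.count for h, _ in excluded)
    )
    phasing.write_phase_table(phased, outdir / "cassette_phase_table.tsv")
    phasing.write_cycle_summary(report, outdir / "cassette_cycle_summary.tsv")
    tallies = locus.coverage_by_region(
        hits21, cassette, threshold=config.display_threshold, strict=config.threshold_strict
    )
    locus.write_region_tallies_tsv(tallies, outdir / "cassette_region_tallies.tsv")
    window_hits = mapper.map_library(
        library,
        cassette.sequence,
        ref_name=cassette.name,
        length_filter=set(range(NON21_WINDOW[0], NON21_WINDOW[1] + 1)),
    )
    ratio_21 = srio.length_class_ratio(window_hits, config.period, NON21_WINDOW)
    max_cycle = max(report.per_cycle, default=0)
    summary["cassette"] = {
        "mapped_reads_21nt": sum(h.count for h in hits21),
        "in_reads": report.in_reads,
        "out_reads": report.out_reads,
        "in_out_ratio": report.ratio.value,
        "in_out_species_ratio": report.species_ratio.value,
        "in_fraction": report.in_fraction,
        "upstream_reads": report.upstream_reads,
        "phase_occupancy": sorted(report.occupancy),
        "populated_inphase_cycles": report.populated_inphase_cycles((1, max_cycle))
        if max_cycle
        else 0,
        "max_cycle": max_cycle,
        "ratio_21_to_non21": ratio_21.value,
        "top_22nt_count": max((h.count for h in hits22), default=0),
    }

    # endogenous genes: transitivity + specific catalog
    if config.genes:
        genes = srio.read_reference_fasta(config.genes)
        fragment = cassette.region_sequence("target_fragment")
        intervals: dict[str, tuple[int, int]] = {}
        if config.gene_fragments:
            bed = pd.read_csv(
                config.gene_fragments,
                sep="\t",
                comment="#",
                header=None,
                names=["ref", "start", "end"],
                usecols=[0, 1, 2],
            )
            intervals = {
                str(r["ref"]): (int(r["start"]), int(r["end"])) for _, r in bed.iterrows()
            }
        summaries: dict[str, locus.TransitivitySummary] = {}
        gene_section: dict[str, dict] = {}
        for gname, gseq in genes.items():
            ghits = mapper.map_library(
                library, gseq, ref_name=gname, length_filter={config.period}
            )
            interval = intervals.get(gname) or locate_fragment(gseq, fragment)
            tsum = locus.transitivity_summary(
                ghits, interval, factor=config.directionality_factor
            )
            summaries[gname] = tsum
            mapper.coverage_bedgraph(ghits, "+", outdir / f"{gname}_21nt_plus.bedgraph")
            mapper.coverage_bedgraph(ghits, "-", outdir / f"{gname}_21nt_minus.bedgraph")
            gene_section[gname] = {
                "fragment_interval": list(interval),
                "upstream_reads": tsum.upstream_reads,
                "within_reads": tsum.within_reads,
                "downstream_reads": tsum.downstream_reads,
                "downstream_species": tsum.downstream_species,
                "verdict": tsum.verdict,
            }
        locus.write_transitivity_tsv(summaries, outdir / "transitivity.tsv")
        summary["genes"] = gene_section

        if config.target_gene and config.homolog_gene:
            catalog = locus.specific_sirna_catalog(
                library,
                genes[config.target_gene],
                genes[config.homolog_gene],
                length=config.period,
                target_name=config.target_gene,
            )
            locus.write_catalog_tsv(catalog, outdir / "specific_catalog.tsv")
            summary["specific"] = {
                "target": config.target_gene,
                "homolog": config.homolog_gene,
                "n_species": catalog.n_species,
                "max_count": catalog.max_count,
            }
    return summary


def check_report_consistency(outdir: str | Path) -> list[str]:
    """Re-derive summary.json headline numbers from the stage TSVs.

    Returns a list of human-readable discrepancies (empty = consistent).
    """
    outdir = Path(outdir)
    with open(outdir / "summary.json") as fh:
        summary = json.load(fh)
    issues: list[str] = []

    hist = pd.read_csv(outdir / "size_histogram.tsv", sep="\t")
    if int(hist["read_count"].sum()) != summary["reads_18_26"]:
        issues.append("size histogram read total != summary reads_18_26")

    table = pd.read_csv(
        outdir / "cassette_phase_table.tsv",
        sep="\t",
        names=["anchor", "phase", "cycle", "strand", "reads", "tag", "note"],
        comment="#",
        header=None,
    )
    down = table[table["cycle"] >= 1]
    in_reads = int(down.loc[down["phase"] == 1, "reads"].sum())
    out_reads = int(down.loc[down["phase"] != 1, "reads"].sum())
    if in_reads != summary["cassette"]["in_reads"]:
        issues.append("phase table in-phase reads != summary in_reads")
    if out_reads != summary["cassette"]["out_reads"]:
        issues.append("phase table out-of-phase reads != summary out_reads")

    tallies = pd.read_csv(
        outdir / "cassette_region_tallies.tsv",
        sep="\t",
        comment="#",
        header=None,
        names=["region", "reads", "species", "species_over_threshold"],
    )
    if int(tallies["reads"].sum()) != summary["cassette"]["mapped_reads_21nt"]:
        issues.append("region tally read total != summary mapped_reads_21nt")

    if "specific" in summary:
        catalog = pd.read_csv(
            outdir / "specific_catalog.tsv",
            sep="\t",
            comment="#",
            header=None,
            names=["sequence", "count", "n_placements", "first_start", "first_strand"],
        )
        if len(catalog) != summary["specific"]["n_species"]:
            issues.append("catalog row count != summary specific n_species")
        max_count = int(catalog["count"].max()) if len(catalog) else 0
        if max_count != summary["specific"]["max_count"]:
            issues.append("catalog max count != summary specific max_count")
    return issues
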