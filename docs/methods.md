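# Methods

## The phase register

MIGS cassettes place a 22-nt miR173 target site between a viral leader and
a target-gene fragment. RISC loaded with a miRNA cleaves its target between
the nucleotides pairing miRNA positions 10 and 11; for a site bound
end-to-end by a miRNA of length L this puts the first nucleotide of the 3′
cleavage fragment at `c = site_start + (L − 10)` (0-based, half-open
coordinates on the transcript strand, used everywhere in this package). For
the 22-nt miR173 site this is `site_start + 12`. A length mismatch between
site and miRNA is refused rather than guessed; callers must then pass an
explicit cleavage override.

Downstream of `c`, Dicer releases 21-nt duplexes head-to-tail. Each duplex
occupies a 21-nt unit anchored at its sense-strand 5′ start `a`; because
Dicer duplexes carry 2-nt 3′ overhangs, the antisense strand of the duplex
anchored at `a` starts at `a − 2` on the reference. Phase assignment
therefore shifts minus-strand hits by +overhang (default 2) before
computing

```
phase = ((a − c) mod 21) + 1        cycle = floor((a − c) / 21) + 1
```

so paired strands share a phase, phase 1 is in-phase with the register, and
cycle 1 is the first unit downstream of the cut. This anchor convention is
the only one under which sense/antisense partners consolidate into one
small-RNA unit, which `consolidate_duplexes` does by exact anchor equality
(an off-by-one antisense read is a different unit, by design).

Conventions fixed here, where the underlying biology does not force a
choice:

* **In-phase means phase 1 exactly.** Near-phase (±1 nt) reads count as
  out-of-phase; they are visible in the per-phase table but never folded
  into the in-phase tally.
* **Ratios are read-weighted** over all downstream cycles to the reference
  end; a species-weighted ratio is emitted alongside for transparency,
  since multi-copy species otherwise dominate.
* **Upstream reads (cycle ≤ 0) are excluded from ratios** — the register is
  only defined downstream of the cut — but are tallied separately, and
  phased + upstream + wrong-length reads always reconcile with the mapped
  hit set.

## Mapping and specificity

Mapping is ungapped perfect matching on both strands: a tag hits where it
equals the reference window (plus strand) or where its reverse complement
does (minus strand). Multi-mapping tags contribute their full read count at
every locus of one reference view; species-level tables count each species
once. IUPAC ambiguity codes in references match no read base. There is no
indel or mismatch tolerance anywhere in mapping — mismatches enter only
through `min_mismatch`, the minimal Hamming distance between a tag and any
same-length window over both strands (vectorised with a numpy sliding
window; a tag longer than the reference reports a "no alignment" sentinel
treated as ≥ 1).

A tag is **homolog-specific** for a target gene when it has an exact
occurrence in the target and `min_mismatch ≥ 1` against the homolog, i.e.
"at least one mismatch" is operationalized as "no exact occurrence on
either strand" — the only reading computable without choosing an alignment
scoring scheme.

Transitivity is summarized by classifying each hit by its 5′-start into
strictly-upstream / within / strictly-downstream of an anchor interval (the
cleavage coordinate on the cassette; the trigger fragment's span on an
endogenous gene, located by exact search or, for diverged paralogs, by the
minimum-Hamming window). The "5′→3′" verdict requires downstream reads to
exceed upstream reads by a configurable factor (default 10×).

Display thresholds ("species cloned more than five times") are report
parameters only — both the value and its strictness (> vs ≥) are
configurable — and are never applied to ratio computations.

## The synthetic generator

`simulate_library` draws the read classes a MIGS line produces; its
defaults are the study conditions the tests and acceptance script run at.

| parameter | default | meaning |
|---|---|---|
| `n_cycles` | 25 | processing cycles attempted downstream of `c` |
| `duplex_mean` | 400 | mean reads of cycle 1 (Poisson) |
| `decay` | 0.7 | per-cycle geometric decay of duplex abundance |
| `slip_prob` | 0.15 | per-cycle-boundary probability of a ±1-nt register slip |
| `strand_bias` | 0.5 | sense share of duplex reads |
| `frac_22nt` | 0.2 | share of cassette duplex reads emitted as 22-mers |
| `secondary_rate` | 2.0 | mean secondary reads per gene position 3′ of the fragment |
| `background_rate` | 50 | mean degradation reads per long reference |
| `identity` | 0.86 | homolog pair identity (i.i.d. substitutions) |
| `precursor_reads` | 3000 | mean total precursor-derived reads |

Design choices:

* **Slip model.** Register drift is a cumulative ±1 random walk realized
  once per library at cycle boundaries (cycle 1 never slips): a
  misprocessing event in one cycle shifts every later cycle, which is the
  simplest mechanism producing accurate early-cycle phasing with growing
  late-cycle drift. The realized offset per cycle is part of the ground
  truth. No quantitative drift rate is claimed for real data; 0.15 with
  decay 0.7 yields majority-in-phase early cycles and mostly out-of-phase
  later ones.
* **22-mers** are emitted at the same duplex anchors with the same overhang
  geometry; the 0.2 share makes the cassette's 21:non-21 read ratio ≈ 4:1
  over the 20–24-nt window, the regime the analyses are aimed at.
* **Secondary siRNAs are unphased** (uniform positions strictly 3′ of the
  fragment, both strands): endogenous transitive siRNAs populate all 21
  phases, and the generator reproduces that without inventing an endogenous
  register.
* **Precursor reads** follow a configurable species profile
  (anchor ∈ {mature, star}, signed 5′ offset, length, proportion). The
  default profile makes a 20-mer shifted 4 nt 5′ of the star the mode
  (64%), with a 21-mer at the same offset second (27.5%), the annotated
  22-nt mature rare (3.1%) and the star nearly absent (0.1%) — a
  low-fidelity processing regime in which the nominal trigger miRNA is a
  minor product.
* **Background** is uniform sense-strand degradation of the long
  transcripts (cassette and genes) at 18–26 nt. The stem-loop gets no
  background class: precursor-derived reads are already their own class,
  and keeping the stem-loop clean lets profile-recovery checks compare
  observed species shares directly to multinomial expectations.
* The default scenario builds a 955-nt cassette (200-nt promoter, 70-nt
  leader, 22-nt target site, 463-nt fragment, 200-nt terminator) around a
  fragment cut from a random 1800-nt gene A, with gene B diverged to 86%
  identity — so the fragment is exact in gene A and diverged in gene B, as
  when a silencing construct is amplified from one member of a gene family.

What the generator does **not** emulate: sequencing errors, adapter
read-through, ligation biases, genuine RNA secondary-structure-dependent
dicing, cis-acting siRNAs that reset the register, or 24-nt heterochromatic
siRNAs. Passing tests on synthetic data therefore demonstrate the
*arithmetic and bookkeeping* of the pipeline (phase assignment, strand
handling, conservation, specificity logic, parameter recovery), not that
real libraries are this clean.

## Numerical and degenerate-input choices

* Ratios with a zero denominator are flagged (`infinite` when the numerator
  is positive, `undefined` when both tallies are zero) rather than raised.
* Profile and catalog orderings are total: descending count, then (start,
  length) or sequence — output is a pure function of the input multiset.
* A tag occurring at several stem-loop positions is assigned its leftmost
  start and flagged, for determinism.
* Empty libraries yield empty (all-zero) histograms and reports, not
  errors; TPM of an empty library is an error (undefined denominator).
* Tests and the acceptance script run at library sizes of roughly 3,000 to
  50,000 reads — large enough for multinomial 3σ checks and coupon-collector
  phase occupancy, small enough that the full suite completes in seconds.

## Known limitations

* Exact matching is literal: a single SNP between the reference and the
  sequenced cultivar silently drops a tag, as with any perfect-match
  criterion.
* The specificity call is binary (exact vs ≥ 1 mismatch); it does not rank
  near-misses or model cross-hybridization.
* Phase statistics assume one register; loci with several initiating cuts
  superimpose registers, and only the configured one is scored.
* The in-phase fraction of a single simulated library has high variance at
  small `slip_prob` because one slip trajectory is realized per library;
  parameter-recovery comparisons therefore average over seeds.
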