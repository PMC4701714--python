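# migsphase

Small-RNA sequencing analysis for **miRNA-induced gene silencing (MIGS)**
experiments. MIGS silences a plant gene by expressing a fragment of it fused
downstream of a 22-nt miR173 target site: miR173-guided cleavage of the
fusion transcript triggers RNA-dependent RNA polymerase / Dicer processing
into **phasiRNAs** — 21-nt siRNAs released head-to-tail in 21-nt increments
from the cleavage site — which in turn silence the endogenous gene(s) and
spawn transitive secondary siRNAs from them.

`migsphase` provides the sequencing-side analysis of such an experiment, for
anyone characterizing a MIGS (or tasiRNA-like) line from an adapter-trimmed
small-RNA library:

* **read collapsing** into unique tags with redundant read counts, with TPM
  normalization and size histograms;
* **perfect-match mapping** of tags onto the expression cassette, the miRNA
  precursor stem-loop, and endogenous genes (both strands, ungapped);
* **phase-register analysis**: each 21-nt hit is assigned a phase
  `p = ((a − c) mod 21) + 1` and processing cycle
  `k = ⌊(a − c)/21⌋ + 1`, where `c` is the predicted cleavage coordinate
  (between the target nucleotides pairing miRNA positions 10 and 11) and `a`
  is the duplex anchor — the sense-strand 5′ start, with antisense hits
  shifted +2 nt so both strands of a Dicer duplex (2-nt 3′ overhangs) share
  one phase. Phase 1 is in-phase; in:out-of-phase ratios, per-cycle tallies
  and phase occupancy summarize register fidelity and drift;
* **precursor processing profiles**: which species a miRNA stem-loop
  actually yields, their abundances, and their 5′-end offsets against the
  annotated mature/star sequences;
* **homolog-specific siRNA catalogs**: siRNAs perfectly matching one gene
  while mismatching every window of its homolog (e.g. an 86%-identical
  paralog), the evidence for transitive silencing of a specific family
  member, plus upstream/downstream transitivity summaries;
* a **synthetic library generator** that emits all of these read classes
  with per-read ground-truth labels, so every stage is testable without any
  sequencing data.

## Worked example

Simulate a MIGS study at the default conditions and run the core analyses:

```python
import migsphase as m

scenario = m.default_scenario(seed=7)          # cassette + homolog pair + stem-loop
params = m.SimulationParams(seed=7)
library, truth = m.simulate_library(
    scenario.cassette, scenario.genes, params, precursor=scenario.precursor
)

hits = m.map_library(library, scenario.cassette.sequence, length_filter={21})
config = m.PhasingConfig(cleavage_coord=scenario.cassette.cleavage_coord)
phased, _ = m.assign_phases(hits, config)
report = m.phase_report(phased, config)

profile = m.precursor_profile(library, scenario.precursor)
catalog = m.specific_sirna_catalog(
    library, scenario.genes["geneB"].sequence, scenario.genes["geneA"].sequence
)
```

This prints (via the obvious f-strings):

```
library: 6642 reads, 1478 unique tags
cleavage coordinate: 282
in-phase : out-of-phase reads = 1060 : 21
in-phase fraction: 0.981
dominant precursor species: 20-mer at star-4, 1995 reads
dominant precursor species: 21-mer at star-4, 821 reads
processing fidelity: 0.028
geneB-specific 21-nt species: 604, max 6 reads
```

Reading the numbers: the cassette's 22-nt miR173 target site ends at
coordinate 292, so the predicted cleavage coordinate (10/11 rule) is 282,
and 98% of the mapped cassette 21-mers sit in phase 1 of that register (this
seed happened to drift late). The precursor is dominated by two species
shifted 4 nt toward the stem-loop 5′ end of the star — not by the annotated
mature product, which is why processing fidelity (the mature+star share of
matched reads) is only 2.8%. The 604 cataloged species match geneB perfectly
while mismatching every window of its 86%-identical homolog geneA, i.e.
they can only have been produced from geneB.

The same pipeline is scriptable from the shell:

```
migs simulate --seed 7 --outdir sim/
migs report --config run.yaml        # see RunConfig keys in migsphase/pipeline.py
```

`migs report` writes one TSV per stage (size histogram, precursor profile,
phase table, per-cycle summary, region tallies, transitivity, specificity
catalog, strand-split bedGraph tracks) plus a `summary.json`, and verifies
that every headline number in the JSON is recomputable from the stage
tables before exiting 0.

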