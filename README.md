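# chromhier

Hierarchical chromatin-architecture analysis for genomes with bimodal
karyotypes (macro- and micro-chromosomes, as in snakes and birds): from
binned Hi-C contact counts to A/B compartments, compartment switches versus
expression, insulation-based TAD boundaries with fixed-width padding, focal
chromatin loops, and histone-mark/expression integration — with a
synthetic-data generator that plants all three structural layers so every
stage can be validated against known truth without external data.

## Who it is for

Researchers analysing chromatin reorganization between tissues or time
points — e.g. a secretory gland before and after stimulation versus a
control tissue — who need a self-contained, reproducible pipeline over
plain-text inputs: sparse-triplet contact counts, a chromosome-size table,
BED gene annotation, a gene/condition expression table, and histone-mark
peak BEDs.

## The methods at its core

* **Normalization** — library scaling to a fixed 1×10⁹ read-pair total;
  per-chromosome ICE (iterative correction) with low-coverage masking;
  observed/expected (O/E) division by the mean contact at each bin
  distance.
* **A/B compartments** (100 kb) — per chromosome, the eigenvector of the
  largest-magnitude eigenvalue of the Pearson correlation matrix of O/E
  rows, oriented so the gene-dense sign is A; per-bin switch
  classification (A→A, A→B, B→A, B→B) between conditions, with a Wilcoxon
  rank-sum test of expression change per switch category against the
  stable group.
* **TAD boundaries** (10 kb) — insulation score
  `log2(windowed mean / chromosome mean)` with boundaries at delta-vector
  zero crossings; each boundary bin padded 40 kb per side to a uniform
  90 kb final boundary; TADs between boundary midpoints; boundary-set
  overlap statistics; feature (gene/DEG) counts and per-Mb densities in
  boundaries vs TADs.
* **Chromatin loops** (10 kb and 25 kb, anchors ≤ 1 Mb apart) —
  donut-filter local backgrounds (donut, lower-left, horizontal, vertical)
  rescaling the decay expectation, Poisson upper-tail test with
  Benjamini–Hochberg correction, single-linkage clustering into loop
  peaks, cross-resolution merging, compartment labelling and loop–gene
  expression coupling at FPKM > 20.
* **Integration** — peak-vs-feature enrichment (bp odds ratio, Fisher-style
  p, permutation z from length-preserving shuffles), strand-aware 1 kb
  promoter statistics, TSS meta-profiles, mark–expression Pearson R, and a
  moderated-t stand-in differential-expression test calling DEGs at
  |log2FC| > 1 and Padj < 0.01.
* **Synthetic generator** — Poisson contact model with planted
  checkerboard compartments, block-diagonal domains and focal loops;
  compartment-biased gene placement and peaks; negative-binomial
  expression with switch-coupled fold changes. See `docs/methods.md`.

## Worked example

The whole pipeline on a self-generated dataset:

```bash
chromhier run-all --outdir out --seed 7
```

or, from Python, stage by stage (this is `examples/04_call_tads.py`):

```python
from chromhier import (make_genome, plant_truth, simulate_contacts,
                       ice_balance, insulation_score, call_boundaries,
                       pad_boundaries, derive_tads)

genome = make_genome(0, 3, None, (8_000_000, 12_000_000), seed=7)
truth = plant_truth(genome, n_boundaries_per_chrom=8, n_loops=0, seed=7)
cmap = simulate_contacts(genome, truth, resolution=10_000, depth=1e7,
                         comp_strength=1.0, tad_strength=2.0,
                         loop_strength=1.0, seed=7)
```

which prints:

```
called 27 boundary bins; recovered 23/24 planted boundaries within +/-1 bin
padded boundaries: every unclipped interval spans [90000] bp (10 kb bin + 40 kb per side = 90 kb)
30 TADs between boundary midpoints, median size 0.83 Mb
```

23/24 planted boundaries are found within one 10 kb bin, every final
boundary is exactly 90 kb wide, and the inter-boundary domains have
sub-megabase sizes, as TADs should. The other scripts in `examples/` cover
simulation (`01`), MAC/MIC interaction comparison (`02` — micro-micro
contacts significantly exceed macro-macro, recovering the planted spatial
clustering of micro-chromosomes), compartment switches vs expression
(`03` — B→A genes show positive median log2 fold change, p < 1e-4), loop
calling (`05` — 50/50 planted loops recovered, all spans ≤ 1 Mb), and
histone-mark integration (`06` — H3ac enriches in A and H3K27me3 in B with
permutation z > 15, and mark–expression R lands on the generator targets
+0.56/−0.45).

Each CLI stage is also exposed individually (`chromhier simulate`,
`normalize`, `compartments`, `switches`, `tads`, `loops`, `integrate`);
`--help` lists the options. A strict YAML config can override any constant
(`chromhier run-all --config run.yaml --outdir out`).

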