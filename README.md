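# barcodekit

Evaluation toolkit for DNA barcode reference libraries.

Given an aligned set of COI (or any single-locus) barcodes with species
labels, `barcodekit` answers the two questions a reference library is built
for — *can an unknown specimen be identified?* and *does the library hint at
undescribed species?* — using the standard battery of distance-based and
tree-based analyses:

- **p-distances** under pairwise deletion, with per-pair overlap control,
  divergence tables (min/mean/max within species and within genera) and the
  95th-percentile intra-specific distance threshold;
- **barcoding gaps**: global gap histograms with the intra/inter overlap
  interval `[min d_inter, max d_intra]`, and per-species local gaps
  (maximum distance to the furthest conspecific vs the nearest-neighbour
  distance);
- **specimen identification** in a leave-one-out protocol under five
  criteria — *best match*, *best close match* and *all species barcodes*
  (distance thresholds, after Meier et al.), plus two tree-based criteria
  (strict monophyly, after Hebert et al. 2003a, and the revised
  cluster-membership criterion of Meier et al. 2006 that tolerates
  paraphyly) — each query scored success / ambiguous / misidentified /
  no match;
- **threshold clustering**: single-linkage transitive closure at fixed
  p-distance thresholds, with threshold-violation counts (chained clusters
  whose internal maximum exceeds the threshold) and *taxonomic accuracy*
  (percent of recognised species forming a perfect cluster);
- **GMYC species delimitation**: the single-threshold generalized mixed
  Yule coalescent model on an ultrametric tree.  The threshold age T\*
  separating speciation (Yule, rate λ₁k) from within-species coalescence
  (rate λ₂·Σⱼ nⱼ(nⱼ−1)) is found by profile likelihood over node ages, with
  a likelihood-ratio test against a single-rate null (χ², 2 df);
- **synthetic libraries**: a Yule-species-tree + Kingman-coalescent
  generator with JC69/K2P/HKY sequence evolution and presets (`clean_gap`,
  `overlapping`, `paraphyly`, `singletons`) whose declared properties are
  verified on the realised data — so the whole pipeline is testable without
  any download.

Trees are `dendropy.Tree` objects; NJ and UPGMA construction from
p-distance matrices, haplotype collapsing, outgroup rooting and newick I/O
are included.  Externally dated ultrametric trees (e.g. from Bayesian
relaxed-clock software) are accepted wherever GMYC needs one.

## Input formats

An aligned FASTA (equal lengths, IUPAC DNA + `-`) and a 5-column TSV with
header `id  species  genus  family  higher_taxon`.  All outputs are TSV /
JSON / newick.

## Worked example

```bash
barcodekit simulate --n-species 5 --n-individuals 4 --preset clean_gap \
    --seed 1 --outdir demo
barcodekit all --fasta demo/library.fasta --metadata demo/library.tsv \
    --min-overlap 300 --thresholds 0.01,0.03,0.06,0.09 --outdir demo/report
```

The first command writes a 20-sequence, 5-species library (663 bp) with a
known truth file.  The second prints a summary (abridged):

```
n_sequences = 20
alignment_length = 663
percentile_threshold = 0.029487
overlap_width = 0.0
global_gap_present = True
n_local_gaps = 5
gmyc_total_entities = 5
gmyc_taxonomic_accuracy = 100.0
cluster sweep (threshold, clusters, accuracy %):
  0.01      7   60.0
  0.029487  5  100.0
  0.03      5  100.0
  0.06      5  100.0
  0.09      5  100.0
```

Read: the realised library has a global barcoding gap (the deepest
within-species distance is below the shallowest between-species distance,
overlap width 0), every one of the 5 species shows a local gap, and both
threshold clustering (at 3–9%) and GMYC recover exactly the 5 simulated
species — 100% taxonomic accuracy.  At a 1% threshold the library
over-splits into 7 clusters (accuracy 60%): two species carry more than 1%
of internal variation.  The same pipeline runs unchanged on a real
alignment + metadata table; `barcodekit --help` lists the per-stage
subcommands (`stats`, `distances`, `gap`, `identify`, `cluster`, `tree`,
`gmyc`).

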