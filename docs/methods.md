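# Methods

This note records the models, conventions and numerical choices behind
`barcodekit`, and what the synthetic benchmarks do and do not demonstrate.

## Distances

The p-distance between two aligned sequences is the fraction of differing
positions among sites where *both* sequences carry an unambiguous base
(A/C/G/T).  Gaps and IUPAC ambiguity codes remove a site for that pair only
(pairwise deletion, the MEGA default for p-distances).  Pairs sharing fewer
than `min_overlap` comparable sites (default 300 of the 663-bp marker;
300–600 supported for sensitivity sweeps) are undefined and excluded from
every downstream summary.  No model correction (K2P, GTR) is applied:
identification thresholds in the barcoding literature are quoted on the
p-distance scale.

Percentiles of the pooled intra-specific distances use linear interpolation
between order statistics — the most common convention; nearest-rank differs
only at small sample sizes.

Composition statistics pool base frequencies over all unambiguous bases.  A
site is conserved iff all unambiguous states present agree (ambiguity codes
count as "not contradicting"), variable otherwise, and a singleton when
exactly one sequence carries a state different from the rest; conserved +
variable partition the alignment length, singletons ⊂ variable.

## Barcoding gaps

The global overlap interval is `[min inter-specific, max intra-specific]`
over defined pairs; a global gap exists iff the interval is empty.  The
overlap fraction is the share of all defined pairwise distances inside the
closed interval.  At genus or higher-taxon grouping, comparisons are
restricted within each group and one report is produced per group.  A
trimmed variant (`trim=0.05`) recomputes the interval after dropping the
extreme 5% of each class — our reading of a "90%" overlap statistic whose
exact definition in legacy tools is not documented; outputs carry the trim
level so the two variants cannot be confused.

The local gap compares, per species with ≥ 2 sequences, the distance to the
furthest conspecific with the nearest-neighbour (closest heterospecific)
distance; singleton species are omitted.

## Identification criteria

All five criteria run leave-one-out: the query's own entry is excluded.
Ties at the minimum distance are kept as a set; a tied set mixing species
is ambiguous (no arbitrary winner).  Threshold comparisons are inclusive
(d ≤ t), so results are bit-stable on rational distances.

- *best match*: species of the closest sequence(s);
- *best close match*: the same, restricted to candidates within the
  threshold; no candidate → no match;
- *all species barcodes*: the set of all sequences within the threshold
  must be non-empty, purely conspecific and complete (every conspecific of
  the query inside) for success — the strict reading of "all conspecifics
  are mutually closer than any heterospecific";
- *strict monophyly* (tree): all members of a species succeed iff the
  species is an exclusive clade (assessed on bipartitions, so root
  placement cannot split a species); singletons are ambiguous; otherwise
  all members are misidentified;
- *cluster membership* (tree): each query is assessed with its tip pruned;
  success when the cluster it joined is purely conspecific, misidentified
  when purely allospecific, ambiguous when mixed or when the species has
  ≤ 2 sequences.  Monophyly is not required, which is exactly what
  separates this criterion from the previous one on paraphyletic species.

Consensus barcodes take the per-site strict majority; gaps win only on
strict majority, base ties become IUPAC codes; the uniqueness check flags
species pairs with identical consensus strings.

## Threshold clustering

Single-linkage transitive closure: two sequences share a cluster iff
connected by a chain of pairwise distances ≤ t (undefined pairs are
non-edges).  Single linkage is forced by the phenomenon being scored: only
chaining can produce clusters whose internal maximum exceeds the threshold
(threshold violations).  Violation percent is per cluster count at that
threshold; taxonomic accuracy is 100 × (perfect clusters) / (recognised
species), a perfect cluster containing all sequences of exactly one
species.  Full precision is kept in outputs; report layers round to two
decimals.

## GMYC (single threshold)

On an ultrametric tree, internal-node ages partition time into inter-event
intervals.  Given a threshold age T, nodes older than T are speciations;
the lineages crossing T define the entities.  Within an interval the
combined branching rate is

    b = λ_yule · k + λ_coal · Σ_j n_j (n_j − 1)

with k the number of species-level lineages (all lineages above T; one
persisting lineage per entity below T — a pure survival term, since no
speciation is observed there) and n_j the lineage count inside entity j.
The branching events form a single exponential race: an interval of width
w ending in an event contributes `b·exp(−b·w)`, the final interval to the
present contributes `exp(−b·w)`, and the root opens the process without
being an event.  The rate-scaling exponents of the general model are fixed
at one.

The likelihood is piecewise constant in T between node ages, so candidates
are exactly the internal-node ages.  Per candidate, the two rates are
fitted by projected Newton ascent on the concave log-likelihood (sum of
logs of linear forms minus a linear form; 200-iteration cap, backtracking
line search, relative tolerance 1e-10).  The null model is the same
waiting-time likelihood with a single rate class; the alternative
reproduces it at the youngest-node candidate, so LR ≥ 0 structurally.  The
LR is referred to χ² with 2 degrees of freedom (second rate class +
threshold).  Known caveats, inherited from the method itself: with very few
species the Yule class contains few events and the test loses power, and a
species whose crown is an outlier against the coalescent scale may be split
— that is the model flagging cryptic structure, not a numerical failure.

Identical haplotypes must be collapsed first (zero-length cherries carry no
rate information); entities are re-expanded through the membership map.
Partitioned analyses (one fit for the whole library, or independent fits
per higher taxon / per family) aggregate entities and score accuracy with
the same perfect-cluster rule; monospecific groups without a tree are
carried as one entity each.  Ultrametricity is checked to 1e-6 absolute on
root-to-tip spans.

## Trees

NJ and UPGMA come from dendropy's distance-matrix methods.  Negative NJ
branch lengths are clamped to zero with the excess moved to the sibling, a
standard repair preserving path lengths; NJ output is stored
midpoint-rooted.  UPGMA supplies the desk-scale ultrametric tree for
delimitation when no externally dated tree is given; it is a stand-in, not
a replacement, for a clock-model tree — users with a Bayesian chronogram
should pass it via `--tree`.

## Synthetic data

The generator composes a Yule species tree (waiting times Exp(k·λ); tips
extended by Exp(K·λ) after the K-th split, making the tree a stationary
snapshot of the process — the correct null for branching-rate tests) with
independent Kingman coalescents inside each species (pairwise coalescence
rate 1/`coal_scale`), grafted at the species tips so the gene tree stays
ultrametric.  The within-species genealogy must fit inside the terminal
branch; draws that do not fit are resampled, which truncates the deepest
coalescences when species branches are short.  Sequences evolve
site-independently under JC69 (default), K2P or HKY with branch lengths in
substitutions/site; under JC69 the expected p-distance at path length t is
(3/4)(1 − e^(−4t/3)), which the tests verify against simulation.

Defaults (663 bp, K = 5, 4 individuals/species, λ = 12, coal_scale = 0.04)
were chosen once to land the realised divergence summaries in the ranges
typical of a squamate COI library — intra-specific means of a few percent
with maxima above 10%, intra-generic means near 20% — and produce the
expected qualitative picture: no global gap, most but not all species with
local gaps, near-perfect best-match identification, modest all-species-
barcodes success, and GMYC oversplitting relative to the nominal species.

Presets verify their declared property on the realised data, retrying with
spawned sub-seeds (≤ 60) and failing loudly with diagnostics otherwise:

- `clean_gap`: max intra < min inter **and** tree-level cleanliness — the
  youngest species split at least 6× older than the oldest species crown,
  and no crown deeper than 5× `coal_scale`.  The second and third
  conditions operationalise "crowns ≪ splits": without them the Kingman
  tail occasionally produces realisations that are not clean in the sense
  the benchmark presumes (a species with a basal divergence deep enough
  that a delimitation method should split it).  Rates: λ = 2, coal_scale =
  0.003.
- `overlapping`: some species' intra-specific maximum exceeds a
  heterospecific distance (realised via shallow species splits — the
  low-interspecific-divergence route to overlap).
- `paraphyly`: one species label is spread over two non-sister clades by
  label manipulation (the most distant non-sister pair is merged), keeping
  the truth exactly checkable; tree cleanliness as in `clean_gap`.
- `singletons`: at least one species with a single sequence.

What passing these benchmarks shows — and does not.  Recovery on
`clean_gap` (20/20 seeds per K ∈ {3,5,8} in our runs) demonstrates
correctness of the machinery under the model's own assumptions: complete
sampling, clock-like evolution, no rate heterogeneity across sites or
lineages, no gene flow, no sequencing error, and genuinely separated
species.  Real libraries violate most of these; the realistic-default
scenario (no gap, oversplitting) is the more honest preview of behaviour
on field data, and the identification-criteria contrasts (paraphyly
handled by cluster membership but not by strict monophyly) transfer
qualitatively, not numerically.

## Degenerate inputs and tie-breaking

Undefined distance pairs: excluded from summaries, non-edges in
clustering, and an error in tree building (trees need a complete matrix).
Species with one sequence: no intra-specific entries, omitted from the
local-gap table, ambiguous under the tree criteria, misidentified or
no-match as the distance criteria dictate.  Empty intra- or inter-class at
a grouping level: the group is absent from the gap report rather than an
error.  Distance ties: resolved by keeping the tied set.  Equal node ages
in GMYC (rare after haplotype collapsing): treated as simultaneous events
over zero-width intervals.
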