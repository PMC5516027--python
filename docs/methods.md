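# Methods

`panflux` implements a comparative-genomics workflow for bacterial pan-genome
dynamics: gene-set quality control, ortholog-family construction, pan/core
accumulation analysis, ancestral gene-content reconstruction with event
classification, parametric detection of horizontally transferred (HGT)
regions, and term enrichment. Every stage can be exercised on synthetic data
with known ground truth, which is how the test suite and the acceptance
script validate the methods. This note records the models, the defaults and
why they are what they are, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## Gene-set quality control

Downloaded bacterial gene sets are screened with three rules before any
comparative step: proteins shorter than 50 aa are removed (a terminal stop
`*` does not count toward the length); genes whose CDS contains an in-frame
stop codon strictly before the terminal codon are removed (a terminal stop is
allowed but not required); and genes whose CDS is more than 30% ambiguous
bases (strictly greater, computed on the CDS, not the protein) are removed.
A CDS whose length is not a multiple of 3 cannot be screened for internal
stops and is removed under its own `frame-error` tag. Protein-only records
are flagged `cds-missing` but retained, since rules 2–3 are defined on the
CDS. Filtering is idempotent and the retained/rejected sets partition the
input.

## Ortholog families

All-vs-all protein similarity uses Smith–Waterman local alignment (BLOSUM62,
gap open −11, extend −1, via Biopython's `PairwiseAligner`) — a desk-scale
stand-in for a BLAST search that is exact rather than heuristic. "Poor
alignments" are removed with two thresholds, both exposed on the CLI: raw
score ≥ 50 and query coverage > 0.5.

The family graph follows the OrthoMCL design: cross-strain edges are
reciprocal best hits (a and b are each other's top-scoring match in the other
strain; ties all kept, which makes the graph order-independent), weighted by
the mean of the two directed scores; within-strain hits above threshold add
paralog edges. Markov clustering partitions the graph: self-loops are added
with each node's maximum incident edge weight (the weighted-graph convention
of van Dongen's MCL), columns are normalized, and expansion (matrix squaring)
alternates with inflation (elementwise power 1.5, then renormalization) until
the largest entry change falls below 1e-6 (cap 100 iterations; entries below
1e-8 pruned between iterations). Clusters are read off as connected
components of the converged matrix's support; genes absent from the graph
become singleton families, so families always partition the retained genes.
Inflation 1.5 is the conventional choice for ortholog clustering; higher
values fragment families.

On simulated families (4 strains, ~30 families, 2% per-site divergence) the
inferred partition reaches adjusted Rand index 1.0 against the generating
families. This shows the RBH+MCL machinery is sound, not that it resolves
the hard cases of real proteomes (domain fusions, promiscuous domains,
very recent paralogs).

## Pan/core accumulation and openness

For each replicate, strains are added in a uniformly random order; `pan(s)`
is the union and `core(s)` the intersection of family sets over the first
`s` strains. Medians over 1,000 replicates summarize the curves. Because
curve values are set cardinalities, the median of an even replicate count is
the lower median (order statistic at ⌈r/2⌉), keeping every summary an
achievable integer. An exhaustive enumerator over all `n!` orders (refused
above n = 6) serves as the oracle; sampled and exact medians agree exactly
on all test fixtures. That equality is only well-posed when the exact median
is probability-mass-interior — a fixture whose median sits exactly on a 0.5
mass boundary makes the sampled median a coin flip — so oracle fixtures are
chosen (and asserted) to have margin > 0.05.

Openness is assessed from the median pan curve: the mean increment
`(pan(n) − pan(1))/(n − 1)`, and a Heaps-law fit `pan(s) ≈ κ·s^γ` by least
squares on log–log scale. The verdict is "open" when the final increment is
positive and 0 < γ < 1. The Heaps fit goes beyond the qualitative openness
argument of classic pan-genome studies and is labelled as an extension in
reports. `shared_fraction` reproduces printed percentages with half-up
rounding to two decimals (599/69,882 → 0.86%).

## Ancestral gene content and events

Family copy numbers are integer characters on a rooted tree, reconstructed
by asymmetric Wagner parsimony (Sankoff dynamic program over states
0..max_count, default cap 10): parent→child transitions cost
`gain_penalty × Δ` for increases and `Δ` for decreases, with gain penalty 1
by default. A family present at the root pays a root-origination cost of
`gain_penalty × root_state`; without it, an all-present family would have
degenerate zero cost at any root state.

Cost ties are broken toward the **largest** count at every node. The choice
matters: at gain penalty 1, "present + one loss below" exactly ties "absent
+ two convergent gains", and since a gene family has a single origin, the
gain-then-loss reading is preferred over convergent gain. The smallest-count
convention (bias toward later gain) was evaluated and discarded: it resolves
every such tie to convergent gains and caps per-branch loss recovery at
~0.63 on simulations. A single-origin family is never mis-assigned by the
largest-count rule because one gain costs strictly less than any
root-present alternative.

Per-branch changes are classified by comparing each node with its immediate
ancestor: gain (0→≥1), loss (≥1→0), expansion (increase, parent ≥1),
reduction (decrease, child ≥1). Each family/branch contributes at most one
event; a 0→c≥2 jump is a single gain, with the copy-number delta kept in a
supplementary column. An exhaustive brute-force enumerator (≤5 internal
nodes, states ≤4) is the oracle: the DP cost matches it on 100 random
fixtures for gain penalties 1, 2 and 3, and the returned assignment is
always among the enumerated optima.

**Identifiability of event recovery.** On simulations (20 taxa, 200 root
families, gain 2.0 per unit branch length genome-wide; loss 0.05, expansion
0.02, reduction 0.02 per family — event density ~0.008 events/family/branch)
per-branch recovery sensitivity is ~0.99 for gains and ~0.93–0.94 for
losses. The loss gap is structural, not algorithmic: a root family lost on
one of the two basal branches leaves exactly the same leaf pattern as a gain
on the opposite basal branch, and the gain reading is strictly cheaper, so
no reconstruction method can recover that loss. The confounded mass is
roughly 2/(2n−2) of losses, which is why sensitivity rises with taxon count
(ceiling ~0.86 at 8 taxa, ~0.95 at 20). The 20-taxon condition is the
package's chosen study size for this experiment.

## HGT-region detection

Two compositional signals are scanned. GC content is computed in
non-overlapping 5 kb windows as deviation from the global genome GC (final
partial window merged into its neighbour when shorter than half a window).
Codon usage is computed in 20 kb windows sliding by 10 kb: a gene
contributes its codons to a window iff the overlap exceeds half the gene's
length (strictly), stop codons and codons containing ambiguous bases are
excluded from numerator and denominator, and each non-empty window yields a
61-dimension frequency vector summing to 1.

PCA of the windows × 61 matrix centers columns but does **not** scale them
to unit variance: frequencies are already commensurate and unit scaling
inflates rare-codon noise. (For reproducing published PC contributions on a
real genome, both conventions should be tried; the choice is recorded in
output metadata.) Outliers on the PC1–PC2 plane are flagged by robust
z-distance — per-axis median and MAD (scaled by 1.4826; fallback to the
standard deviation when the MAD is zero), Euclidean combination — above 3.5.

Runs of flagged windows (tolerating one unflagged window inside a run) are
merged into region calls, with two structural rules:

* **Minimum support of 3 windows.** With half-overlapping windows a single
  anomalous 10 kb cell flags exactly two windows, so 2-window calls are
  indistinguishable from one-cell noise; 3 is the smallest support a single
  cell cannot produce. This matters quantitatively: with ~200 windows per
  2 Mb genome the maximum of ~200 correlated robust distances sits near 3.3,
  and at minimum support 2 about a quarter of composition-uniform genomes
  produce a spurious call, while at 3 none of 100 null simulations do.
* **Flank trimming.** The outermost half-window of a run is corroborated by
  only one window, so calls of ≥3 windows report the ≥2×-covered core (the
  span from the second window's start to the second-last window's end).
  This is what brings boundary error within one step (~3 kb mean) instead
  of up to a full window.

On the default study condition — 2 Mb host genome at GC 0.5305 carrying a
150 kb donor region at GC 0.4597, the GC contrast of the published
*Paenibacillus* sp. SSG-1 island, with donor/host codon profiles built by
exponentially re-weighting the uniform 61-codon profile to the target GC —
the planted region is recovered in 50/50 seeds with mean boundary error
~3 kb, and composition-uniform genomes yield zero calls in 100/100 seeds.
The synthetic genome is deliberately simple (uniform gene lengths and
spacing, no rRNA/tRNA/repeat structure, single contig), so these rates show
the scan's behaviour under a clean compositional contrast, not its
false-positive rate on real chromosomes with rRNA operons and phage remnants.

For two-genome corroboration, `anchor_match` chains exact k-mer matches
(k = 21, unique in both genomes, both strands of the second) that are
collinear within a 2 kb gap tolerance, dropping chains spanning under 5 kb.
It is a simplified stand-in for a whole-genome aligner: exact matches only,
greedy chaining, no extension across SNPs — sufficient for near-identical
shared islands, not for diverged homology.

## Enrichment

Per term, the 2×2 table of target/background against term membership is
tested with the one-sided (enrichment) Fisher exact test, i.e. the upper
hypergeometric tail P(X ≥ a), followed by Benjamini–Hochberg correction with
significance at adjusted p ≤ 0.05. The multiple-testing family m counts
every term with at least one background gene (restricting to terms
intersecting the target is available but off by default — it shrinks m
selectively). Term sets are flat: no GO-DAG propagation or elim-style
decorrelation. Under a null in which targets are drawn uniformly from the
background, the mean significant fraction over 1,000 draws is ~0.001–0.01,
comfortably below the nominal 0.05 (BH is conservative here because the
per-term tables are discrete and the terms overlap little).

## Synthetic-data generator

The generator inverts each inference problem.

* **Tree**: random topology by repeated joining of uniformly chosen
  subtrees; branch lengths Exp(mean 0.1) + 0.01 floor. Deterministic per
  seed.
* **Gene content**: Gillespie simulation along each branch with four event
  types. Gains arrive genome-wide at `rate_gain` per unit branch length and
  draw fresh ids from an unbounded pool (no re-gain of a lost family), so
  ground-truth recovery is free of homoplasy ambiguity; loss, expansion and
  reduction act per eligible family (loss needs count ≥1, reduction ≥2).
  The exact per-branch event log is returned and replays to the leaf
  profiles — an invariant the tests assert.
* **Family sequences**: one ancestral CDS per family (100–300 codons,
  uniform sense codons, ATG start); each leaf copy receives binomial
  codon-level substitutions at `1 − exp(−rate × root-to-leaf distance)`,
  resampled to avoid creating stops, so emitted proteins pass QC by
  construction. Leaf copies are mutated independently from the family
  ancestor (a star approximation within families) — adequate for testing
  clustering, not for testing tree inference, which is out of scope.
* **Genome with island**: genes of 100–500 codons alternate with 60–200 bp
  intergenic gaps across a single contig; segments whose midpoint falls in
  the nominal donor interval draw codons (and intergenic bases) from the
  donor profile, everything else from the host profile. The reported
  planted region is snapped to the first/last donor segment, making the
  compositional contrast exact at its boundaries. Defaults (2 Mb genome,
  150 kb region, GC 0.5305 vs 0.4597) mirror the published genome-vs-island
  contrast at a desk-scale genome size.

All generators are deterministic per `(config, seed)` down to byte-identical
FASTA/GFF3/Newick output, which the CLI's manifest hashes verify.

## Problem sizes

Test-suite and acceptance-script experiment sizes are the package's chosen
study conditions: 50 seeds for event recovery (20 taxa × 200+ families),
50 planted + 100 null genomes of 2 Mb for the HGT scan, 100 random fixtures
× 3 penalties for the parsimony oracle, 1,000 replicates for accumulation
sampling and 1,000 draws for enrichment calibration. The published headline
counts that depend on the 76 real proteomes (69,882 families, 599 core,
1,833 ancestral families, mean 862 pan increment, the 65.96%/6.13% PC
contributions of the real chromosome) are not reproducible from synthetic
data and are used only as printed-arithmetic inputs or generator targets.

## Known limitations

* The aligner-based all-vs-all step is O(n² ) in gene count and meant for
  desk-scale inputs; large studies should import an external 12-column hit
  table instead (`read_hit_table`).
* Wagner parsimony caps copy numbers at 10 by default; higher counts are
  truncated with a warning.
* Basal-branch losses of root families are structurally unidentifiable (see
  above); reported loss sensitivity excludes nothing, so it reflects that
  ceiling.
* The HGT scan is parametric only; recent transfers from compositionally
  similar donors, or anciently ameliorated islands, are invisible to it, as
  are transfers detectable only by phylogenetic conflict.
* Enrichment treats terms as flat sets; hierarchically nested GO terms will
  co-fire.
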