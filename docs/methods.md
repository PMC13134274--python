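# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `follireg3d`.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open internally; 1-based
GTF-style gene tables are converted on read.  Strand is carried through
BED round-trips but ignored by interval arithmetic (regulatory elements
are strandless); motif scanning handles both strands explicitly.
Element signal is the base-weighted region mean of the bedGraph track
(uncovered bases count as 0), not a summit value.  Contact matrices are
per-chromosome and cis-only; all in-scope 3D statistics are cis.

## Differential expression

Inputs are pre-normalized non-negative abundances with ≥ 2 replicates
per stage.  The per-gene test is a Welch two-sample t-test on
log2(x + 1), Benjamini–Hochberg-adjusted across all genes; log2 fold
change uses stage means with pseudocount 1 (zero-expression stages are
common in stage-specific genes).  This is a deliberate, documented
simplification of a negative-binomial count model: it is well calibrated
on the log-normal synthetic data, and its null behaviour is verified by
Monte-Carlo in the suite, but it is *not* a drop-in for count-based
inference on raw RNA-seq counts.  A gene is called differential when
|log2FC| strictly exceeds 1 (a ≥ variant is available via
`strict_lfc=False`) and FDR < 0.05.  With zero within-group variance
the Welch statistic is undefined; the implementation assigns p = 1 when
the group means agree and p = 0 when they differ, which makes the
noiseless limit of the generator exactly recoverable.

Expression clusters are K-means (k = 8 by default, k-means++ with 50
restarts, best by within-cluster SS, fixed seed) on per-gene z-scored
log2 stage means; flat genes get σ → 1 in the z-score so they remain
assignable.

The specificity index is the τ statistic,
`TSI = Σ_i (1 − x_i/x_max) / (n − 1)`, computed by default on
log2(x + 1) stage means (0 = flat, 1 = single-stage; an all-zero
profile is 0 by convention).  τ is exactly scale-invariant on linear
profiles; the logged variant is the reported one because expression
spans orders of magnitude.  Cliff's delta is the exact all-pairs
statistic.

## Super-enhancers and super-silencers

Peaks are stitched when gaps are ≤ 12,500 bp (the ROSE convention; the
study does not print its stitching parameters, so the tool default is
adopted and both the distance and an optional TSS-exclusion window are
configurable — TSS exclusion is off by default).  A region's signal is
Σ(constituent length × constituent mean signal), a BAM-free
approximation of read load; stitching conserves total signal and is
idempotent.  Regions are ranked by signal, both axes min–max scaled,
and the cutoff placed where the ascending curve lies furthest *below*
the diagonal — the slope-1 tangent point of the hockey stick — with
ties resolved toward the higher cutoff (fewer supers).  Regions
strictly above the cutoff signal are super.  Because min–max scaling
absorbs any positive affine map, the super count is invariant under
affine rescaling of all signals; arbitrary monotone warps (log, square)
change the curve's shape and are not expected to preserve the knee —
this is true of any tangent-rule cutoff.  Identical machinery applied
to H3K27me3 yields super-silencers.  Stage-specific elements are whole
elements with zero overlap against every other stage (elements are
never clipped), and "dynamic" enhancers are those gained or lost
between any adjacent stage pair; a signal-fold-change definition can be
substituted upstream by filtering the per-stage element sets.

## Hi-C statistics

Balancing is plain iterative proportional fitting (20 iterations,
tolerance 1e-5) — a deliberately simple stand-in for a full ICE
implementation that equalizes informative row sums.  Resolution QC is
the fraction of bins whose raw row sum strictly exceeds 1,000 contacts.

Compartments: observed/expected by per-diagonal means, Pearson
correlation matrix of the O/E, leading eigenvector; the sign is
oriented so bins positively correlated with a gene-density (or mean
expression) track are "A".  Zero-coverage bins are "NA"; a uniform
matrix degenerates with a warning.

Insulation: per-bin mean of the 10×10 square of contacts spanning the
bin, log2-ratioed to the chromosome mean of that statistic and
z-scored; edge bins inside the window are NaN.  The ratio makes the
track invariant to global count scaling.  Boundaries are local minima
with prominence ≥ 0.1 z-units (plateau ties resolve to the leftmost
bin).  On ideal block matrices the minimum is a two-bin plateau at the
joint, so all boundary matching uses ±1 bin.

Stage-specific boundaries follow a two-criterion test.  Criterion 1:
no boundary of any adjacent stage within ±1 bin (±20 kb).  Criterion 2:
the Spearman correlation between the two stages' insulation values in
the ±10-bin (±200 kb) window centered on the boundary must not exceed
the 95th percentile of a null built from 1,000 windows at uniformly
random bins of the same track pair (one-sided upward: high ρ means the
local landscape is shared).  Both adjacent stages must be
non-significant.  The window signal is the insulation score itself;
the per-pair null quantile and per-boundary ρ are reported.  With the
three Hi-C stages the adjacency is the sampled order SYF→F5→F1.

Intra-TAD strength is the mean balanced (or raw) contact among bin
pairs inside a TAD, diagonal excluded; TADs under 2 bins are NaN.
Loop calls from several resolutions are integrated by re-binning anchor
midpoints at 25 kb and collapsing identical bin pairs (max score kept) —
a deterministic midpoint rule rather than interval overlap, which makes
merging idempotent.  Distal enhancer–gene links require one anchor to
overlap the enhancer and the other a promoter (TSS ± 2 kb by default)
by ≥ 1 bp each.

## Network inference

Candidate enhancer–gene pairs are limited to pairs whose enhancer
midpoint and gene TSS share a TAD (TADs from the insulation boundaries
of the first Hi-C stage).  Pearson r across all stages present in both
inputs (7 by default; with n stages the exact-t p has df = n − 2, so
seven points give limited power per pair — redundancy across an
enhancer cluster is what makes the planted circuit recoverable), BH
across all tested pairs genome-wide, FDR < 0.05 retained.  Constant
vectors are skipped and counted.

PWM scanning is a log-odds scan against the background frequencies at
every position on both strands; a hit needs ≥ 0.8 of the motif's
maximum achievable score, and N-containing windows are skipped.
Motif enrichment binarizes sequences (≥ 1 hit) and applies a one-sided
hypergeometric test of target hits against a disjoint background set
(pass the complement of the target set); TFs at P < 1e-5 (uncorrected,
matching the printed threshold) yield TF–enhancer pairs.

The network is strictly tripartite; a TF→gene path exists iff some
enhancer carries both edges.  Stability is the mean fraction of
original paths surviving when ⌊0.1·E⌋ edges are removed uniformly at
random (100 trials, seeded) — the removal fraction, trial count and the
statistic itself are package definitions, since "stability score" has
no standard formula.  The permutation test rewires each bipartite layer
with degree-preserving double-edge swaps (10×E attempted swaps per
layer per replicate, 1,000 replicates) and compares the distinct
TF→gene path count two-sidedly: a redundant circuit (several enhancers
carrying the same TF to the same gene) has *fewer* distinct paths than
its degree-preserving null, so a one-sided upper tail would be blind to
exactly the planted topology; the empirical two-sided p is
min(1, (1 + 2·min(#{null ≥ obs}, #{null ≤ obs}))/(n + 1)).

Core TFs satisfy two criteria: (1) motif enriched (P < 1e-5) in
dynamic enhancers vs the static complement, and (2) the TF is
differential in ≥ 1 adjacent-stage contrast *and* at least 30%
(`co_min`) of its targets share the TF's expression cluster.  The 30%
co-clustering fraction is a package choice — no published fraction
exists — and is configurable.

Variant mapping is a two-step join: locus → overlapping enhancer →
genes linked to that enhancer.

## The synthetic-data generator

The generator emulates the study design: 7 ordered stages with 4
expression replicates, chromatin elements for all 7 stages, Hi-C at
SYF/F5/F1, loops at 10/20/25 kb.  Default genome: 2 chromosomes × 10 Mb
at 20 kb bins.  All randomness flows from one seed through named
substreams (layout, expression, elements, hic, loops, sequences, gwas),
so regeneration is byte-identical and single layers can be reproduced.

* **Expression.** 8 log2-scale archetypes (one peak per stage plus a
  hierarchical-high F5/F3/F1 profile), baseline 3 and peak 9, ~50 genes
  each plus flat background genes at log2 = 5; replicates add N(0, 0.3)
  log-normal noise.  Planted DEG directions derive from the noise-free
  archetype means.
* **Elements.** 800 enhancers of 600 bp.  A planted circuit of 10 TFs ×
  3 target genes × 4 enhancers lives inside large interior TADs (one
  target per TAD; bystander co-expressed genes are kept out of circuit
  TADs because a genuinely co-expressed neighbour would create real but
  unplanted correlations).  Circuit enhancer activity follows its
  target's archetype; core-TF enhancers are present only at their peak
  stages (hence dynamic), the rest are static; decoy enhancers carry
  independent per-stage noise.  SE/SS regions are clusters of 4
  high-signal constituents (1.5 kb each, 3 kb gaps, well inside the
  stitch distance) planted as shared or stage-specific.
* **Hi-C.** Mean contact = depth × (1 + d)^−0.8 × 3^[same TAD] ×
  1.5^[same compartment], Poisson-sampled and symmetrized.  The depth
  scale (150 at distance 1 → row sums in the several-thousand range) is
  a realism choice consistent with the deep-coverage QC the method
  applies (and leaves insulation dips well above shot noise).  TAD
  sizes are 14–24 bins (~280–480 kb); compartments alternate every two
  TADs (the checkerboard); five TADs per chromosome acquire a mid-TAD
  joint in exactly one Hi-C stage (the planted stage-specific
  boundaries), the remaining ~50 joints are shared.
* **Loops.** 30 true loops connect a dedicated enhancer bin to a
  promoter bin (both 25 kb bins reserved so no other feature lands in
  an anchor), reported at all three resolutions with anchors that
  re-bin consistently; 60 decoy loops sit in feature-free bins.
* **Sequences and motifs.** 30 PWMs (10 circuit + 20 decoy TFs) with
  mutually distant consensi (Hamming ≥ 4) and 0.9 consensus
  probability; at the 0.8 score threshold only exact consensus matches
  hit, so chance hits are ~5·10⁻² expected per motif across all 800
  sequences.  Two consensus copies are planted per circuit enhancer.
* **GWAS.** 12 of 40 loci fall inside circuit enhancers; the rest in
  feature-free positions.

What the generator does **not** emulate: mapping and peak-calling
artifacts, copy-number and coverage biases, trans contacts, compartment
switching between stages, overlapping/nested regulatory elements,
sequence composition beyond i.i.d. background, and the weak, partially
correlated effect sizes of real data.  Passing the recovery suite
therefore demonstrates the correctness and calibration of the
algorithms under their stated assumptions — not their field performance
on real sequencing data.

## Problem sizes and determinism

The default test and acceptance configuration uses the 2 × 10 Mb
genome, 600 genes, 800 enhancers, 7 × 4 expression samples and 1,000
permutation draws; the full acceptance run completes in about a minute
on one CPU.  Every stochastic operation takes an explicit seed and is
bit-reproducible; the CLI writes the effective configuration and
record counts next to every output.

## Known limitations

* The Welch-on-log substitute is anticonservative for low counts with
  strong mean–variance coupling; real count data should be analysed
  with a count model upstream and fed in as normalized abundances.
* Pearson correlation over 7 stage means has low per-pair power; links
  supported by a single enhancer and modest correlation will be missed
  at FDR < 0.05.
* The tangent-rule SE cutoff is scale- but not warp-invariant, and is
  sensitive to the signal distribution's tail.
* Balancing is plain IPF; heavily biased matrices may need a real ICE
  implementation upstream.
* The stability score and the rewiring-null path-count statistic are
  package definitions of otherwise under-specified quantities; both are
  reported with their parameters so they can be compared across runs.
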