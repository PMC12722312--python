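# Methods

This note documents the models and procedures implemented in `csrscope`,
the defaults and why they were chosen, what the synthetic data emulate, and
the numerical conventions that matter for reproducibility.

## The measurement model

A CSR junction amplicon runs from a forward primer upstream of Sμ, through
the donor breakpoint, and continues at the acceptor breakpoint in a
downstream switch region to that region's reverse primer. A long read over
such an amplicon therefore aligns as two (or more) blocks: one ending at
the donor breakpoint in Sμ, one starting at the acceptor breakpoint.
Everything the package computes derives from those per-read block patterns:

* the **coverage pattern** of a read over the concatenated switch regions
  identifies its clone — two reads from the same clone cover the same
  intervals, up to sequencing noise;
* the **gap** between covered intervals locates the junction (donor
  position = last covered donor base, acceptor position = first covered
  acceptor base);
* the **sequence at the junction** records repair chemistry (microhomology,
  untemplated nucleotides);
* **signed coverage** records structural aberrations (≥2 = tandem
  duplication, negative = inversion), and blocks mapping outside the switch
  regions flanked by switch blocks are **templated inserts**.

## Reduced coordinates

Switch regions are concatenated into a reduced coordinate system; each
region's offset is rounded up to the next multiple of 500 nt so that 50 nt
breakpoint bins never straddle a region boundary (padding positions carry
`N` and never receive coverage). Rounding is applied per region, not only
to the total, which guarantees unambiguous binning for any region-length
configuration.

## The simulator

The simulator is the package's study-condition generator, not a test prop:

* **Clone tables**: donor breakpoints uniform inside Sμ, acceptor region
  uniform among the seven acceptors, acceptor breakpoints uniform inside
  the region (100 nt margins). A minimum pairwise donor-breakpoint
  separation can be requested for constructing well-separated fixtures.
* **Copy numbers**: Poisson with mean *k* (default), or fixed.
* **Noise**: independent per-base substitution, insertion and deletion
  rates; indel events have geometric lengths (mean 1.5 nt, capped at
  20 nt), with event rates scaled so the *base-level* rates match the
  configuration. Two presets ship: `nanopore-like` (3% / 2% / 3%) and
  `hifi-like` (0.2% each). The error model of the original measurement was
  trained on a non-PCR plasmid control that is not available here; the
  presets encode the same regime (noise dominated by small indels) as
  configuration. Noise is applied per template segment, so truth blocks
  carry exact noisy-read coordinates.
* **Synthetic locus**: one contig with Sμ (3,000 nt) and seven acceptor
  regions (1,500 nt each) at 65% GC separated by 45%-GC spacers, primer
  sites flanking each amplicon, plus a decoy contig for templated inserts.
  Region lengths are multiples of 500 by default.
* **Quality strings** are constant per preset; the pipeline only uses base
  qualities for optional read filtering.

What the simulator does **not** emulate: PCR chimeras and jackpot
amplification, basecaller-specific error profiles, context-dependent error
rates, biological hotspot structure of real switch repeats (AID targeting),
and germline polymorphism (unless planted). Passing tests therefore
demonstrate correctness of the algorithms under the stated error model,
not performance on any particular real platform.

## Demultiplexing

Motifs (barcodes, primers) are found by iterated banded edit-distance
search (edlib, infix mode) in both orientations: the best match is
recorded and masked, and the search repeats until nothing within the edit
band remains. The identity threshold is 0.75 (edit band =
`len(motif) × 0.25`); matches are full-motif alignments, so motifs
truncated below ~0.7 of their length at read ends are not reported.
Equivalence with the original short-match tool settings is at the contract
level (hits found/missed), not score level.

Hits wholly more than 100 nt from both read ends are *internal* (strict
inequality). Internal primer hits only count against a read when their
identity is at least 0.85: an expected motif at a read end needs less
evidence than a surprising one deep inside a read, and at identity 0.75 a
24-nt motif matches somewhere in a multi-kilobase read by chance alone.
Concatemer splitting groups hits within 250 nt; an internal cluster with
two or more hits is split at the midpoint between a reverse-oriented hit
and the following forward-oriented hit (the inward-facing adapter
boundary), falling back to the widest intra-cluster gap.

## Read filtering

Rules are applied in a fixed order and the first failure is the reason
code: too short (<500 nt, matching amplicon sizes ≥1 kb); missing
forward/reverse primer; internal primer; fewer than two switch-region
alignments; genome span < 0.5 × read span ("mapped regions much shorter
than the read"); any pairwise block overlap > 25 nt on read or genome;
mapped fraction < 0.9; switch blocks out of genome order; undetermined
isotype. The 0.5 span factor and 25 nt overlap are package choices exposed
in `FilterConfig`; the 25 nt value matches the gap scale used for
rearrangement calling.

The isotype is the non-Sμ region with the largest overlap of the
right-most block; ties go to the downstream region.

## MSA encoding

Cell value `m = 10·coverage + base` with **floored** integer division for
decoding (`m // 10`, `m % 10`), stated explicitly because truncated
division would decode negative coverage inconsistently (−8 must decode to
coverage −1, base C). Per-base genome correspondence within a block comes
from a global edlib re-alignment of the read segment to its genomic
segment; genome bases deleted from the read surface as micro-gaps. At a
duplicated position the consensus base is taken from the left-most
covering block. Samples are capped at 50,000 reads by a seeded uniform
subsample (seed in `ClusterConfig`).

## Clustering

Coverage rows are cleaned by filling gaps strictly smaller than 75 nt
(the "smaller than" is strict: a 75 nt gap is kept), suppressing indel
artefacts. Distances are cosine; all-zero rows are defined to be at
distance 0 from each other and 1 from any non-zero row (they should not
occur post-filter but must not crash).

* **Dense UPGMA** uses `scipy.cluster.hierarchy.linkage` on the full
  distance matrix (computed via BLAS in float64, so identical rows merge
  at exactly 0). It is validated against a hand-written O(n³) oracle to
  1e-12.
* **Sparse linkage** builds a k-nearest-neighbour graph (k = 20):
  candidate neighbours are ranked on a column-binned (25 nt) version of
  the matrix for speed, then exact full-resolution cosine distances are
  computed for candidate pairs only. Agglomeration follows UPGMA's
  weighted-average update restricted to existing graph edges; when only
  one side of a merge knows a neighbour, that distance is reused
  unchanged. Exactness is not claimed — the contract is partition
  agreement with dense UPGMA (ARI ≥ 0.95) at the working cutoff.
  Disconnected components merge at maximal height.

The dendrogram is cut at 0.01 by default; `find_cutoff` can instead scan a
range and return the point of maximal distance from the chord connecting
the curve extremes (default), or the crossing point of a double-exponential
fit `a·exp(−b·c) + d·exp(−e·c)` (non-default; the functional form is a
package choice). A flat curve degenerates to the scan midpoint with a
warning.

Cluster filtering flags clusters in order of increasing size (ties: larger
root-node height first, i.e. more isolated) and stops before retained
reads would drop below 95% — retention ≥ 95% is a hard postcondition.

Diversity measures are computed on 10 subsamples of 1,000 reads
(replicate r uses seed + r) and averaged: post-filter cluster count, Gini,
entropy (natural log, so `clusters_eff = exp(entropy)` is self-consistent;
computed pre-filter), inverse Simpson, occupancy of the top clone and of
clusters above 1% of reads, and mean/sd of cluster size fractions.

## Junction realignment

With donor block ending at read position p and acceptor block starting at
q ≥ p, the donor genomic continuation is extended rightward from p and the
acceptor genomic upstream leftward from q, gapless, stopping at the first
mismatch (up to 20 nt, truncated at read ends). With gap g = q − p and
extensions d and a, the slack d + a − g is the microhomology when
positive; when negative, the uncovered junction bases are untemplated.
The two are mutually exclusive by construction, and planted values are
recovered exactly at zero noise. Junctions at read boundaries are marked
undefined and excluded from context features. Gap-affine scoring presets
(per platform) remain in the configuration for reproducibility of the
block boundaries when ingesting external alignments.

## Variant calling and haplotyping

Per position, observed base counts are tested against the expectation from
the reference base and a uniform error rate by a chi-square
goodness-of-fit test (df = 3); candidates need p below 0.05 Bonferroni-
corrected over tested positions and an excess non-reference base.
Filters (all flags recorded; any flag excludes):

* gap proximity: > 70% gap frequency among spanning reads in a centered,
  inclusive 10 nt window (truncated at edges);
* Poisson minor-AF: alternate count within the 99.9th percentile of
  Poisson(error × depth) — quantile is a package choice, the model is not;
* strand bias: 2×2 chi-square p < 0.05 **and** relative +/− difference of
  alternate reads > 0.125;
* cluster support: excluded only when *no* retained cluster of ≥10 reads
  has allele frequency > 0.4 **and** the total allele frequency is < 0.4,
  so cluster-confined somatic variants survive.

Haplotyping factorizes the cluster × variant alternate-count matrix
(clusters with ≥10 reads) at rank 2 by multiplicative-update weighted NMF
(weights = per-position cluster coverage; 500 iterations or relative
tolerance 1e-6). 100 restarts (restart r seeded seed + r) yield a
consistency score = fraction of restart pairs with identical cluster
partitions; a split whose two components have indistinguishable
allele-frequency profiles (within 0.05) is collapsed to a single group so
the degenerate all-homozygous case is consistently scored 1.0.
Classification: allele frequency > 0.6 in both components → homozygous
germline; in exactly one → heterozygous germline; otherwise likely
somatic. Variant statistics are reported alongside, not inside, the
68-feature vector.

## Breakpoint matrix and features

Gaps ≥ 75 nt from reads in retained clusters enter a 2D histogram of
(donor, acceptor) positions in 50 nt bins. Default weighting is
cluster-equal: each gap carries 1/cluster-size, so the matrix total equals
Σ (breaks in cluster / cluster size) exactly; read-equal weighting is
available. Each break falls in exactly one of five categories — direct
switch (Sμ → other), sequential switch (two non-Sμ regions), intra-switch
deletion, inversion-linked, duplication-linked (an inversion/duplication
event of the same read within 25 nt of the gap) — so the five percentages
sum to 100.

Package choices where the feature definitions were open:

* **bin homology** (for `homology_score_fw/rv`): length of the longest
  exact common substring between 50 nt bin sequences (forward, or against
  the reverse complement), normalized by bin length, isolated in
  `longest_common_substring`;
* **motif set**: weak/strong single-base classes W = A/T, S = G/C and the
  AID hotspot WRCY (donor side) / RGYW (acceptor side), counted per base
  in each bin and weighted by 1D breakpoint frequencies;
* **complexity**: Shannon entropy of bin 3-mer frequencies;
* **adjusted cluster size**: exp of the residual of log(size) regressed on
  consensus length and GC across clusters (amplification bias proxy);
* **fragment length/GC**: consensus length and GC per cluster, aggregated
  cluster-first.

Cluster-specific quantities are always averaged within clusters first and
then across clusters, making sample-level features independent of clonal
expansion. Undefined features (e.g. dispersion of a region with no breaks)
are NaN, never 0. The 68-name manifest with category assignments
(5 + 17 + 28 + 9 + 9) ships as package data.

## Downstream analysis

Feature tables are z-scored per feature (constant features dropped with a
warning; training parameters stored). Held-out samples are normalized
*independently* with their own parameters and rotated into the training
principal components. Classification is L2 (ridge) logistic regression
with the regularizer chosen by stratified cross-validation
(folds = min(10, smallest class size), seeded); the argmax of class
probabilities decides the label.

## Problem sizes and numerical notes

Default working sizes are those used throughout the documentation and
checks: 5,000-read samples for full-pipeline runs (dense or sparse
clustering), 10,000 reads per sample for the clone-count recovery
analysis with sparse linkage, 2,000 reads for two-allele fixtures, and
1,000-read subsamples for diversity. The acceptance script simulates both
of its samples from scratch at these sizes.

Ties in UPGMA merges follow scipy's deterministic ordering (dense) or the
heap order of equal distances (sparse); both are reproducible across runs.
All randomness flows through explicit seeds (`numpy.random.default_rng`),
and replicate/restart seeds are derived as seed + index.

## Known limitations

* The sparse linkage is approximate beyond the kNN horizon; very diffuse
  samples with thousands of singleton clones may see small partition
  differences from dense UPGMA (the ARI ≥ 0.95 contract is tested at
  2,000 reads).
* Junction realignment uses gapless extensions; microhomology interrupted
  by a sequencing error is truncated at the error.
* The SNV caller assumes a uniform substitution error rate; platform
  context effects inflate the candidate list and are handled only by the
  downstream filters.
* Sequential-switch detection requires the intermediate region to be
  covered by the read; fully resected sequential events are counted as
  direct switches.
* Feature values on synthetic data should not be compared numerically to
  real-sample values: the synthetic locus has random (not repeat-rich)
  switch sequences, which lowers motif and homology scores.
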