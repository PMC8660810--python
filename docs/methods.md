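# Methods

This note documents the models, conventions and numerical choices behind
`crossoccupy`, and what the synthetic validation does and does not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). GTF records
(1-based closed) are converted at the parser; nothing downstream ever sees a
1-based coordinate. Chromosome names are matched as exact strings — no "chr"
aliasing — so a mismatched assembly fails loudly rather than silently
producing empty joins. bedGraph is the canonical track serialization: one
record per maximal run of equal-valued bins, which makes write→read an exact
round trip (asserted in tests).

narrowPeak summits are `start + offset`; an offset of −1 (peaks called
without summit reporting) falls back to the interval midpoint so the
summit-inside-interval invariant always holds.

## Peak processing

Summits are extended ±100 bp (200 bp regions). Reproducibility across two
replicates is a reciprocal per-peak test: a peak survives when at least
`min_frac` (default 0.5) of **its own** length is covered by its best single
partner in the other replicate. Survivors from both replicates are
union-merged (overlapping or bookended intervals); the merged region's summit
is its midpoint and its score the maximum of its constituents, since a merge
has no unique summit. A `rep1`-anchored mode returns surviving replicate-1
peaks unmerged, for workflows that want one replicate's coordinates.

Cross-cell-type classification uses the best single-partner overlap (BEDtools
`-f`-style semantics, not summed across partners): shared means ≥ 10 bp,
anything less — including bookended neighbours at overlap 0, regardless of
threshold — is cell-type-specific. The partition is exhaustive, disjoint, and
symmetric under swapping the two sets; the indexed implementation is tested
against an all-pairs oracle.

## Coverage tracks and profiles

A bin's value counts fragments overlapping it by ≥ 1 bp (not a per-base
mean); at 10 bp bins the difference is immaterial and the count definition is
exactly testable against a naive double loop. z-normalization uses the
*population* SD pooled over all bins of all chromosomes, zero bins included —
this keeps the three-bin example [2, 4, 6] → [−1.2247, 0, 1.2247] exact and is
indistinguishable from the sample SD at genome scale. Scaffold/mitochondrial
exclusion is assumed to have happened upstream, at fragment filtering.

A peak's z score is the mean z over the bins its interval overlaps (the
summit-bin value is a defensible alternative; region mean is the default
because 200 bp regions span 20 bins and the mean is stabler). Profile
matrices read the track bin containing each column's start position
(columns step by one bin width from summit − flank); bins outside the
chromosome contribute 0 and are flagged rather than dropped, keeping the
column count fixed at 2·flank/bin_width (120 at defaults).

## Motif scanning

Matching is set-membership per position against the IUPAC class of each
pattern base. `N` in the *genome* matches nothing, including pattern `N` —
assembly gaps must not create motifs. Minus-strand hits are found by scanning
the reverse-complemented pattern on the forward sequence, so every reported
start is a forward-strand leftmost coordinate; this makes the ±200 bp
summit-window rule strand-agnostic. Both strands are scanned by default (the
tally convention is ambiguous in general practice; a forward-only flag
exists). Region tallies require the match fully inside the region.
Rank-binned fractions sort by z score descending with (chrom, start)
tie-breaks; the final partial bin is kept and its fraction uses its own size.

## Feature annotation

Classification is by summit position with fixed priority promoter > 5'UTR >
3'UTR > exon > intron > downstream > distal intergenic, so each peak gets
exactly one class and class counts sum to the peak count (the pie-chart
arithmetic). The promoter window is −500..+150 around the TSS measured along
the gene; "downstream" extends 1 kb past the 3' end (a convention that must
be fixed somewhere; it is configurable). Nearest gene minimizes |summit −
TSS| with lexicographic gene-id tie-break; distances are signed in gene
orientation (negative = upstream). The randomized background preserves each
region's chromosome and length and re-places it uniformly; enrichment against
it uses the two-sided Fisher test below. Because annotation-tool precedence
rules differ, absolute class percentages from other annotators are not
expected to reproduce exactly; directions of enrichment are.

## Statistical tests

**Fisher exact (two-sided)** uses the point-probability definition — the sum
of hypergeometric probabilities of tables (same margins) no more probable
than the observed one, with a 1e-7 relative tolerance on the comparison, the
convention of the R ecosystem. Verified against exact-fraction enumeration
for every table with margins ≤ 12. Odds ratios use the sample OR with a
Haldane 0.5 correction when a cell is zero.

**Wilcoxon rank-sum** enumerates the exact null over all group assignments
(midranks, so ties are handled) when the pooled size is ≤ 20, counting
assignments whose rank-sum deviation from the null mean is at least the
observed one; otherwise it uses the normal approximation with tie-corrected
variance and 0.5 continuity correction (within 0.01 of a 10^5-resample
permutation oracle at n = 30).

**Replicate correlation** is Pearson's r on log2(count + 1); the pseudocount
is configurable since the raw-log convention is undefined at zero.

## Time-course model

Counts `y_rj` for region r, sample j (timepoint t(j), size factor `s_j` from
median-of-ratios over all-positive regions) are modelled NB2:
mean `μ s_j`, variance `μ s_j (1 + α μ s_j)`. The full model fits one mean
per timepoint, the reduced model one common mean; the statistic
Λ = 2(ℓ_full − ℓ_reduced) is referred to χ² with T − 1 df and BH-adjusted
across regions. Group means are MLEs computed by damped Newton on the score
(closed-form `Σy/Σs` when exposures are equal; a handful of iterations
otherwise), vectorized across regions. All-zero regions get p = 1 and a flag.

**Dispersion.** The per-region moment estimator works on the normalized scale
q = y/s and pools unbiased within-timepoint variances:
α̂_r = Σ_t (v_t − q̄_t·mean(1/s)) / Σ_t q̄_t², floored at 1e-8. The unbiased
(ddof = 1) variances matter: with one fitted mean per group, raw residual
moments are biased low by half at two replicates, which would roughly double
the LRT. Even unbiased, a 10-observation estimator is noisy, and plugging it
in makes the χ² reference anticonservative (regions with underestimated α̂
dominate the tail). The default therefore takes the **maximum** of the
per-region estimate and the pooled all-region moment estimate — the
conservative rule of the first-generation count-model packages, with no
empirical-Bayes shrinkage. With the true dispersion plugged in the test is
exactly calibrated; with the max rule the null rejection rate at p < 0.05 is
within the 3–7% band on the 2,000-region reference simulation, and the
sensitivity cost relative to the known-dispersion oracle is bounded in the
test suite (≤ 0.15 at the reference conditions). `per-region` and `pooled`
modes remain available, as does a fixed-dispersion override whose α → 0
limit reproduces the closed-form Poisson LRT exactly.

A caveat the tests make explicit: with two replicates per timepoint and
moderate overdispersion (α = 0.1, μ = 50), a maximum fold change of 2 is near
the detection floor — the known-dispersion oracle itself only reaches ~0.8
sensitivity at the archetype profiles (up to 3.3-fold) and essentially zero
at a strict 2-fold rescaling. Detection claims at small effect sizes should
be read against that information limit, not against the estimator.

## Trajectory clustering

Input vectors are replicate-averaged size-factor-normalized counts per
timepoint, z-scored per region (constant rows become zero vectors); shapes,
not levels, drive the clustering. k-means is Lloyd's algorithm with
Euclidean distance, distinct-point initialization, best of nstart = 25
restarts by within-cluster SS, empty clusters re-seeded at the farthest
point, and a per-iteration assertion that the objective never increases.
Results are deterministic given the seed. The raw-trajectory (non-z-scored)
mode is exposed for sensitivity analyses.

Cluster groups for the binding-enrichment test are defined by the sign of
(mean of last two − mean of first two) centroid timepoints. Note transient
shapes end near where they start, so this endpoint rule can place a
"transient loss" cluster in the increasing group; the closure tests plant
truth according to the rule itself.

## Synthetic data generator

The generator is first-class, tested code; its guarantees are literal:

- **Genome**: random sequence at GC 0.43 (2 × 500 kb by default), 60 simple
  gene models with exons and UTRs.
- **Peak sets**: anchor slots spaced ≥ 700 bp (windows cannot interact).
  Shared pairs are planted with 100–190 bp mutual overlap (always ≥ the
  10 bp rule); unique peaks have zero cross-condition overlap; shared counts
  are exact, not expected values.
- **Motifs**: positive peaks receive a concrete realization of the IUPAC
  motif inside the peak region (hence within 200 bp of the summit);
  negative windows (summit ± 200 plus motif length) are rejection-sampled
  until motif-free on both strands, keeping base composition realistic
  rather than masking. A constant rate plants an exact count; the gradient
  mode plants Bernoulli flags with probability linear in z rank.
- **Accessible regions**: an exactly counted fraction (default 0.92) of one
  condition's peaks get an overlapping 500 bp accessible region, plus
  background accessible regions.
- **Fragments**: lengths from f·N(60, 15) + (1 − f)·N(200, 25) truncated to
  [20, 500] (nucleosome-free vs mono-nucleosome modes); midpoints uniform
  with rate ratio ρ inside accessible regions (ρ = 1 is a homogeneous
  background, giving Poisson per-region counts); a configurable fraction of
  MAPQ ≤ 30.
- **Time courses**: five timepoints (0–24 h), two replicates, NB counts at
  base mean 50 and dispersion 0.1 by default, with six fixed archetype
  profiles (early/late/transient increase/loss; e.g. early loss =
  1, 0.4, 0.3, 0.3, 0.3) and a planted changing fraction. Archetype means
  are fixed constants so recovery tests are reproducible.

What passing the closure tests shows: the pipeline recovers exactly what the
generator planted, under the generator's assumptions. What it does not show:
robustness to features of real data the generator omits — mappability and
GC bias, duplicate reads, copy-number structure, peak-width heterogeneity,
correlated replicates, mean-dependent dispersion trends, and genuine genome
annotation complexity (overlapping genes, alternative TSSs).

## Problem sizes

Reference simulations are sized to be decisive yet quick: 500 peaks per
condition for classification closure, 2,000 peaks for the motif gradient
(20 rank bins), 2,000 regions for LRT calibration and recovery, 600
trajectories for clustering recovery, 20,000 fragments for filter retention.
These sizes give binomial standard errors well inside the asserted
tolerances.
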