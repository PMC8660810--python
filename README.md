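# crossoccupy

Cross-cell-type analysis of pioneer-factor occupancy and chromatin
accessibility, for regulatory genomicists comparing where a transcription
factor binds in two cell states and how accessibility at those sites changes
over a differentiation time course.

Pioneer factors such as Zelda can engage nucleosome-occluded DNA, but their
genomic occupancy is still reshaped by cell-type-specific chromatin. Comparing
ChIP-seq peak sets between cell types — and relating binding to ATAC-seq
accessibility over time — requires a chain of small, exactly specified
operations: summit-centered peak regions, reproducibility filtering across
replicates, overlap-based classification into shared and cell-type-specific
sites, genome-wide z-score coverage tracks, degenerate-motif tallies,
promoter/feature annotation, and count-based time-course inference. This
package implements that chain as a tested library, and pairs it with a
synthetic-data generator that plants known truth so every stage can be
validated end to end without any sequencing data.

## The core operations

- **Peak post-processing** — narrowPeak summits extended ±100 bp to 200 bp
  regions; a peak is *reproducible* when ≥ 50% of its length overlaps a peak
  in the other replicate (survivors union-merged); a peak is *shared* between
  two cell types when its best single-partner overlap is ≥ 10 bp, otherwise
  cell-type-specific.
- **z-score tracks** — fragment coverage in 10 bp bins, standardized
  genome-wide: z = (c − mean(c)) / sd(c) pooled over all bins; summit-centered
  profile matrices (±600 bp, 120 columns) and average profiles.
- **IUPAC motif scanning** — both-strand degenerate-motif matching (e.g.
  CAGGTARV, ACMGRG, AAAWGVVCMNH), per-region presence tallies, presence within
  ±200 bp of a summit, and motif fractions in rank bins of 100 peaks ordered
  by z score.
- **Feature annotation** — summit-based classification with promoter defined
  as TSS −500..+150 (strand-aware), fixed priority promoter > 5'UTR > 3'UTR >
  exon > intron > downstream > distal intergenic; nearest-gene assignment;
  randomized-background enrichment via Fisher's exact test.
- **Time-course differential accessibility** — nucleosome-free fragments
  (length < 100 bp, MAPQ > 30) counted over regions; median-of-ratios size
  factors; per-region negative-binomial likelihood-ratio test of
  per-timepoint means μ_t against a common mean μ (χ², T − 1 df,
  BH-adjusted), with a conservative moment-based dispersion; k-means
  (Lloyd, nstart = 25) over z-scored trajectories into six archetypes
  (early/late/transient increase or loss), with binding-enrichment and
  motif-stratified decay comparisons.

The time-course model follows the statsmodels convention:
`AccessibilityTimeCourse(counts).fit()` returns a results object with the
per-region table, `summary()`, and `.cluster()`.

## Worked example

```python
import crossoccupy as co

world = co.make_world(seed=17)                      # synthetic genome + truth
result = co.classify_cross_condition(world.peaks_a, world.peaks_b,
                                     label_a="embryo", label_b="neuroblast")
print(result.summary())
frac = co.overlap_fraction_with_set(world.peaks_b, world.accessible)
print(f"peaks overlapping accessible chromatin: {100 * frac:.1f}%")

counts, truth = co.make_timecourse(n_regions=2000, changing_fraction=0.3, seed=17)
results = co.AccessibilityTimeCourse(counts).fit()
print(results.summary())
clusters = results.cluster(k=6, nstart=25, seed=17)
print("cluster sizes:", clusters.labels.value_counts().sort_index().to_dict())
```

prints

```
embryo: 200 shared, 300 unique | neuroblast: 200 shared, 300 unique (>= 10 bp best-partner overlap)
peaks overlapping accessible chromatin: 92.0%
Time-course differential accessibility (NB likelihood-ratio test)
regions: 2000   timepoints: [0, 6, 12, 18, 24]   df: 4
size factors: t0_r1=1.030, t0_r2=1.000, t6_r1=1.027, t6_r2=1.030, t12_r1=1.001, t12_r2=1.041, t18_r1=1.026, t18_r2=1.037, t24_r1=1.007, t24_r2=1.006
significant at BH FDR 0.05: 413 (20.6%)
median dispersion: 0.0985
cluster sizes: {1: 95, 2: 88, 3: 52, 4: 53, 5: 48, 6: 77}
```

The generator planted a 0.4 shared fraction (200 of 500 peaks per condition)
and 92% accessible overlap, both recovered exactly; of the 30% of regions
planted as truly changing, 413 are called at BH FDR 0.05, and the six k-means
clusters correspond to the planted trajectory archetypes.

A thin CLI wraps the same functions: `crossoccupy simulate-world`,
`classify`, `track`, `profile`, `motifs`, `annotate`, `dynamics`.

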