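# Methods

This note documents the models, parameter choices, and numerical details
behind `acetylink`, and what the synthetic-data-driven tests do and do not
establish about real data.

## Coordinate conventions and I/O

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is shifted at the boundary by subtracting 1 from the
start only.  A gene's TSS/TES are strand-aware single positions: on the
minus strand the TSS is `end − 1`, so TSS > TES in genomic coordinates.
Gene length for FPKM is the union of exon intervals.  Chromosome names
pass through verbatim — there is no "chr" normalization, so a mismatch
between a track and an annotation surfaces as zero coverage (with a
warning) rather than a silent rename.  Coverage tracks are piecewise
constant runs; gaps mean depth 0; overlapping runs are rejected at read
time.

## Quantification and normalization

Peak signal is the sum of per-base depth over the interval (bedcov
semantics), additive over partitions and checked exactly against a
per-base oracle.  Consensus peaks come from merging all samples' calls
with gap ≤ 0 (book-ended intervals merge, matching `bedtools merge`).

Low-expression filtering drops a gene when the number of samples with
count < 2 reaches `ceil(0.8 · n)` — with six samples, 5 of 6.  The
ceiling reading was chosen because "80 % of samples are low" must actually
be satisfied, not approached from below (4.8 of 6 is not a sample count).

Size factors are plain median-of-ratios: factor_j = median over zero-free
features of `count_ij / geomean_i`, rescaled to geometric mean 1.  When no
zero-free feature exists the code falls back to total-count ratios with a
warning.  FPKM uses exon-union length and raw per-sample totals
(`count · 10⁹ / (length · total)`), the standard definition; size factors
are applied only inside the differential test and to peak signal used for
correlation.

## The differential test

The test is deliberately simple: one construction shared by genes, peaks,
and stitched super-enhancers.

1. Normalize: k̃ = k / s_j.
2. Fold change: `log2FC = log2((mean_B + ½)/(mean_A + ½))`.  The ½
   pseudocount keeps fold changes finite at zeros.
3. Dispersion: per-feature method of moments,
   `α_g = (var_g − mean_g)/mean_g²` computed within each group and pooled
   with weights (n_g − 1), floored at 10⁻⁸.  No shrinkage across features.
4. Wald statistic: `W = log2FC / SE`, with
   `SE² = [(m_A + αm_A²)/n_A]/(m_A + ½)² + [(m_B + αm_B²)/n_B]/(m_B + ½)²`
   divided by ln²2 (delta method for log2 of a mean under
   Var = μ + αμ²).
5. Reference distribution: **Student t with n_A + n_B − 2 df**, the
   residual degrees of freedom behind the pooled dispersion estimate.
   With three animals per group a standard normal reference is visibly
   anticonservative — the moment dispersion estimate is noisy at 4 df, and
   measured null fractions of p ≤ 0.05 were ≈ 0.12 under the normal
   reference versus ≈ 0.05 under t₄.  The t reference is this package's
   choice for honest calibration at small n; it converges to the normal as
   group sizes grow.
6. BH step-up adjustment (via statsmodels) is reported alongside; calls
   use the *raw* p-value by default (`use_raw_p=True`), matching the
   stated thresholds (|log2FC| ≥ 1, p ≤ 0.05 for genes and peaks;
   |log2FC| ≥ 0.6, p ≤ 0.05 for super-enhancers), with adjusted-p calling
   available behind the flag.  All threshold comparisons are closed.

All-zero features get p = 1 and log2FC = 0.  Feature order never affects
results.

## Four-way peak–gene classification

Peak→gene assignment is nearest TSS by peak-midpoint distance within
50 kb (configurable), ties broken by lexicographically smaller gene id.
Correlation is Pearson between size-factor-normalized peak signal and gene
FPKM across the six animals (ChIP and RNA samples of the same group are
matched by sample-sheet order — the same animals were profiled with both
assays).  Normalized scales avoid depth-driven spurious correlation.  A
zero-variance vector makes r undefined; it is reported as 0 with a flag,
which can never pass the |r| ≥ 0.5 bound.

The quadrant of a pair is determined by the *gene's* expression fold
change and the correlation sign: PP (up, positive), PN (down, positive),
NP (up, negative), NN (down, negative), all closed comparisons at
|log2FC| ≥ 1 and |r| ≥ 0.5; pairs meeting neither bound are "none".  Only
peaks that themselves pass the differential-peak thresholds enter the
genome-wide table.  The quadrant map is a partition; flipping the fold
change swaps PP↔PN and NP↔NN, flipping r swaps PP↔NP and PN↔NN.

## Super-enhancers

The chain follows the established stitching-and-ranking recipe with its
conventional defaults, both configurable: TSS exclusion ± 2,500 bp
(a peak is removed if its interval overlaps any TSS window) and stitch
distance 12,500 bp (gap ≤ distance merges, transitively).  Region signal
is `max(0, Σ chip − Σ input)` over the stitched span; a missing input
track degrades to chip-only with a warning.

The cutoff sits at the slope-1 tangent of the rank–signal curve: sort
signals ascending, min-max scale both rank index and signal to [0, 1], and
take the signal at the first index whose forward discrete slope exceeds 1.
This discrete rule is well defined on ties and plateaus, invariant to
positive affine transforms of the signal, and yields *no* super-enhancers
for curves that never exceed slope 1 (e.g. perfectly linear ranks) — a
straight line has no privileged class.  A vector with fewer than 3 values
or zero range also yields none.  Regions above the cutoff are
super-enhancers; ranks (1 = strongest) break ties by genomic position so
calls are independent of input order.

Differential SEs: per-sample SE intervals are merged within each group
(an empty group degrades to the other group's regions with a warning),
group sets are unioned and merged into one feature set, every sample's
chip coverage is quantified over it, and the shared NB test runs at the SE
thresholds.  Size factors should come from a genome-wide feature set (the
pipeline passes the consensus-peak factors): the median-of-ratios over a
handful of partly-differential SE regions is unstable.

## Metaprofiles and sample correlation

Reference-point matrices average depth in fixed 50 bp bins over
[anchor − flank, anchor + flank), anchor = TSS or TES, flank 3 kb or 1 kb
presets per figure convention.  Scale-regions matrices bin fixed-width
flanks plus the gene body rescaled to a fixed number of windows; bodies
shorter than the bin count use fractional (real-valued) windows integrated
exactly against the piecewise-constant track.  Minus-strand rows are
reversed so upstream is always left.  Profiles are exactly linear in the
track and bins beyond a chromosome edge count missing bases as depth 0.

Sample correlation is Spearman (average ranks, then Pearson on ranks) on
raw counts, or Pearson on log2(x + 1); computed on the consensus-peak
matrix for ChIP and the gene matrix for RNA.  Zero-variance samples yield
NaN rows/columns with a warning.

## Cross-species intersection

DEG tables are keyed on upper-cased symbols; an explicit source→target
ortholog map may be applied first (no automated ortholog inference —
database-dependent and out of scope).  Duplicates after mapping keep the
smaller p.  Venn regions are exact set algebra; counts over all membership
patterns sum to the union size.  Direction concordance (same log2FC sign
everywhere) is reported but not required for membership, since conserved
gene sets legitimately mix up- and down-regulated genes.

## qPCR statistics

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the arithmetic
mean ΔCt of the control group (chosen over per-pair baselines; the mean
makes the control group's mean ΔΔCt exactly 0, hence its geometric mean
fold exactly 1); fold = 2^(−ΔΔCt), monotone decreasing in ΔΔCt.  Group
comparison is Welch's t-test with Satterthwaite df (the safer default when
variances may differ; the pooled Student variant is behind a flag).  Two
constant equal groups give t = 0, p = 1.  Stars: *** p ≤ 0.001,
** p ≤ 0.01, * p ≤ 0.05, closed boundaries.

## The synthetic-data generator

The generator emulates the 3-vs-3 high-fat-diet design; its defaults are
the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_chroms × chrom_length_bp` | 2 × 500 kb | 1 Mb genome |
| `n_genes` | 200 | single-exon genes, 1 kb, alternating strands |
| `n_samples_per_group` | 3 | animals per diet group |
| `effect_log2fc` | 2.0 | planted differential effect (genes and peaks) |
| `nb_dispersion` | 0.1 | NB dispersion α (Var = μ + αμ²) |
| `mean_count` | 200 | gene-count scale; per-gene baseline lognormal(0, 1) |
| `background_depth` | 1.0 | coverage baseline |
| `peak_enrichment_fold` | 8 | promoter/distal enhancer over background |
| `se_enrichment_fold`, `peaks_per_se` | 10, 5 | SE cluster strength/size |
| `frac_se_clusters` | 0.025 | shared SE clusters per gene count (→ 5) |
| `n_group_specific_se` | 1 | treatment-only cluster (the differential SE) |
| `n_distal_enhancers` | 16 | background singles forming the rank-curve tail |
| `link_correlation` | 0.9 | peak–gene latent coupling ρ |
| `library_sd_log` | 0.1 | lognormal per-sample depth (exercises size factors) |

Layout: genes occupy the first 60 % of each chromosome, uniformly spaced
with jitter; distal enhancers and SE clusters live in the gene-free tail,
placed ≥ 5 kb past the last gene with > 12.5 kb gaps so TSS exclusion
cannot erase them and distinct elements never stitch together.  Each gene
carries a TSS-centred 1 kb promoter peak with probability 0.9, with a 2×
summit over the central 100 bp so metaprofiles peak at the TSS; the summit
scales with the peak's fold, keeping group ratios exact.  Coverage is
Poisson per-base noise aggregated into 50 bp runs (tractable file sizes);
input tracks are background only.  Counts are negative-binomial with fixed
dispersion — exactly the differential test's assumption — and the
decades-wide lognormal baseline reproduces the high intra-group sample
correlations seen in real expression data.

Peak–gene links: for a linked pair the peak's per-sample log2 shift is
group effect + N(0, 0.5²) jitter; the gene's shift is
`ρ · peak_shift + √(1−ρ²) · noise`.  ρ (`link_correlation`) therefore
controls both the planted Pearson correlation and how much of the peak's
fold change the gene inherits (ρ · 2 at the defaults), so link recovery
degrades smoothly as ρ drops — the behavior the four-way analysis is
tested against.  Links pair differential promoter peaks with their own
gene: a deliberate simplification of the correlation structure the
four-way analysis assumes, not a mechanistic enhancer model.

qPCR tables are built so that 2^(−ΔΔCt) recovers the planted fold up to
Gaussian Ct noise (sd 0.1 cycles by default).

Everything draws from one seeded generator threaded through all stages; a
config fully determines the dataset, files round-trip through the readers,
and the pipeline output is byte-identical across reruns.

**What passing tests do not show:** the generator has no GC or
fragment-length bias, no read-level artifacts, no mappability gaps, no
multi-exon structure, no inter-gene correlation beyond planted links, and
uniform dispersion.  Recovery rates measured here are upper bounds on what
the same thresholds achieve on real libraries; published SE counts and
genome-wide quadrant totals depend on the real sequencing data and are not
reproduction targets at this scale.

## Problem sizes used in checks

Stochastic checks run at compact sizes chosen to exercise the estimators,
not to mimic sequencing depth: null calibration on 2,000 NB features;
sensitivity/FDR on 50 replicates of 300-gene genomes; link recovery on 50
replicates of 60-gene genomes; SE recovery and differential-SE detection
on 20 seeds of the full 200-gene fixture.  The end-to-end fixture is the
1 Mb / 200-gene / 6-sample study.

## Known limitations

* The NB test has no dispersion shrinkage, Cook's-distance filtering, or
  independent filtering; it is a calibrated small-sample approximation,
  not a DESeq2 reimplementation.
* Peak→gene assignment is nearest-TSS; no 3D-contact or loop-based
  assignment.
* Calling on raw p (the default) does not control FDR across features;
  the BH-adjusted column is always reported and can drive calls instead.
* The slope-1 tangent is computed on the discrete curve; very small
  region sets (< 3) or constant signals yield no super-enhancers by
  definition.
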