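# Methods

## Data model and conventions

All analyses consume per-CpG read counts (`count_meth`, `count_unmeth`) per
sample.  Coordinates are internally 0-based half-open; Bismark coverage
files are read as 1-based inclusive and converted.  A CpG is identified by
the plus-strand position of its C; plus/minus records at positions p and
p + 1 are merged by summing counts onto p (on by default — the two strands
of a CpG are treated as one site; disable with `strand_merge=False` /
`--no-strand-merge` if calls were already merged upstream).  Read counts
are authoritative; the methylation-percentage column of coverage files is
derived and only checked for consistency.

## Window methylation

The genome is tiled with sliding windows of `size_bp` = 3000 advanced by
`step_bp` = 600 (the published configuration); the final window of each
chromosome is clipped at the chromosome end.  A window qualifies when it
contains at least `min_cpg` = 5 distinct covered CpG sites (sites, not read
observations).  The window level is the binomial maximum-likelihood
estimate — the pooled methylated-read fraction, equivalently the
observation-weighted mean across sites — with a Wilson score interval
attached for reporting only; nothing downstream consumes the interval.
A site on a window boundary belongs to the window iff pos ∈ [start, end).

## Cell-to-bulk variance and noise correction

For each cell, qualified windows are inner-joined with the bulk's and the
heterogeneity statistic is the weighted variance of the cell's window
levels around the bulk's, with weights wⱼ = the cell's read observations in
window j.  The weight definition is a design choice: the cell side carries
the information (bulk depth is an order of magnitude larger), so windows
the cell measured better count more.

Sparse coverage alone produces variance, so a noise floor is estimated by
downsampling: at every site present in both samples, the cell's depth is
drawn without replacement (hypergeometric) from the bulk's reads, yielding
a pseudo-cell with exactly the cell's covered-site set and per-site depths
but no biology of its own; the same variance statistic on
pseudo-cell-vs-bulk, averaged over `n_rep` = 20 replicates (the replicate
count is a package default; "multiple" downsamplings are prescribed without
a number), is the noise estimate.  The corrected variance is
max(raw − noise, 0); negative estimates are Monte-Carlo artifacts.
Because the pseudo-cell inherits the cell's site profile, the noise
estimate correctly includes site-composition sampling (a sparse cell sees a
subset of each window's CpGs), not just read-level binomial noise.

One subtlety, visible in the null tests: downsampling replicates share the
bulk's *realized* reads at partially methylated sites, so their spread
understates the full Monte-Carlo error of raw − noise; the residual
fluctuation scales with the partial-site fraction and vanishes exactly when
no partial sites exist.  Null checks therefore use the across-cell spread
of the corrected variance, not the replicate spread.

### Group tests

Group differences in mean corrected variance are tested by permutation:
the statistic is mean(A) − mean(B); all C(|A|+|B|, |A|) relabelings are
enumerated when that count is within the permutation budget (p = count /
total, the observed split being one of the enumerated ones), otherwise
Monte-Carlo relabelings are drawn with the add-one convention
p = (count + 1)/(n + 1) so p is never 0.

### Differentially methylated windows

A window is a DMW when |m_cell − m_bulk| ≥ 0.3 **and** a two-sided binomial
test of the cell's pooled window counts rejects after Benjamini–Hochberg
control at α = 0.05 across tested windows.  The binomial null probability
is the bulk level computed over the CpG sites the cell covers in that
window, not the full-window bulk level: a sparse cell sees a subset of a
window's sites, and when sites within a window differ in state the cell's
pooled counts deviate from the full-window level through composition
sampling alone; testing against the shared-site bulk level removes that
artifact (the effect-size filter still uses the full-window difference).
Both thresholds are exposed (`--effect-min`, `--alpha`); the DMW definition
as a whole is this package's concretization — reasonable alternatives exist
and the defaults were chosen to control the no-signal case (a cell
resampled from its own bulk yields zero DMWs).  DMW testing is per cell;
group-level summaries average per-cell frequencies.

## Epivariation calling

An epivariation is a methylation difference between one cell and its bulk
at a single CpG.  A site is *eligible* when (1) sequencing depth exceeds
`min_depth` = 5 in both cell and bulk and (2) more than `bulk_consistency`
= 90 % of bulk reads share one methylation pattern; it is *called* when
additionally (3) more than `min_divergent` = 3 cell reads carry the
opposite pattern.  All three cut-offs are strict inequalities.  An exact
50/50 bulk has no majority pattern and is ineligible.  The headline
frequency is 100 · called / eligible — a rate per assayable site, which is
the quantity recovered in simulation; the variant with all
cell/bulk-overlapping sites in the denominator is also emitted since the
two readings of "total CpGs analyzed" differ.  The per-site direction
(methylation gain vs loss) is retained for downstream use but not
summarized.  `sensitivity_scan` re-runs the caller over a grid of nearby
criterion settings to verify the estimate is stable.

## Feature stratification

Bins (non-overlapping 3-kb windows by default) receive every feature label
whose interval overlaps them by ≥ 1 bp; unlabeled bins are intergenic, and
generic "promoter" labels are resolved to promoter_CGI / promoter_nonCGI by
CGI overlap.  To remove coverage and sample-size bias, each bin in each
cell is downsampled to exactly `target_obs` = 5 pooled read observations
(drawn without replacement from the bin's reads, irrespective of how many
sites contributed them; bins with fewer observations are excluded for that
cell), then the `n_cells` = 10 cells with the highest pre-downsampling
observation count are retained per bin (ties broken by sample id for
reproducibility; bins with fewer qualifying cells are dropped).  The bin
variance is the equal-weight mean squared deviation of the retained cells'
downsampled estimates (each averaged over `n_rep` = 20 replicate draws)
from the bulk level; class summaries are means over the bins carrying each
label, reported absolute and relative to the all-bin mean.  The mean is the
primary per-class statistic; the per-class dispersion is emitted alongside
for interval construction.  Cells are pooled across groups before ranking.

## QC

Conversion efficiency is 100 · (1 − methylated/total) over non-CpG cytosine
observations, which are assumed truly unmethylated in these cell types;
samples below a configurable floor (98 %) are flagged.  A site is
"partially methylated" when its observed level lies strictly within
(`partial_low`, `partial_high`) = (0.1, 0.9) — the numeric definition is
this package's choice and is CLI-exposed.  Note the classification is
depth-sensitive: at depth ~2 a single conversion-failure read yields level
0.5, so shallow samples' partial fractions are only comparable at matched
depth or with conversion failure absent.  `merge_cells` sums counts
site-wise (union of sites); merged-vs-bulk concordance is reported as the
Pearson correlation and mean |Δm| over up to 10,000 randomly sampled
qualified paired windows.  The promoter-panel identity test computes each
sample's observation-weighted mean 5mC over a panel of promoters (the
per-promoter-averaged variant is also emitted) and compares groups with a
Welch t-test, one-tailed by default (target group hypomethylated relative
to the reference).

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with ground truth retained for parameter recovery:

- **CpG placement**: a renewal process with geometric gaps (mean
  `cpg_spacing_mean` = 100 bp, minimum 2 bp), ≈ 10 CpGs/kb as in mouse.
- **Bulk truth**: each site independently partial with probability
  `f_partial` = 0.0107 (level ~ Beta(5, 5), a symmetric allelic-mixture
  distribution), otherwise methylated with probability `p_methylated` = 0.7
  (level 1) or unmethylated (level 0) — a bimodal methylome with ~70 %
  global 5mC and ~1 % partial sites.
- **Cells**: every non-partial site switches state independently with
  probability ε (`epsilon` = 0.033 by default; a per-site array supports
  feature-stratified rates).  Partial sites never switch — the epivariation
  concept contrasts a near-homogeneous bulk with a divergent cell, and
  partial bulk sites fail the 90 % consistency rule regardless.
- **Reads**: covered-site depth is Poisson truncated at ≥ 1 (bulk mean 30;
  cells cover each site with probability `cell_site_coverage_prob` = 0.2 at
  depth mean 2, emulating the ~10× site-coverage gap between single cells
  and bulk).  Methylated counts are Binomial(depth, p) with p the effective
  level inflated by `conv_fail` = 0.015 (an unmethylated cytosine reads as
  methylated with that probability; 98.5 % conversion efficiency).  Non-CpG
  tables contain `n_noncpg_sites` positions whose reads are methylated only
  through conversion failure.
- **Features**: non-overlapping blocks per class tiled as a repeating 10-kb
  cassette (promoter [CGI on alternate cassettes] + H3K4me3, exons +
  H3K36me3, intron, UTR, LINE, H3K4me1, LTR, SINE, intergenic remainder).
  Only relative per-class stratification is analyzed, so no attempt is made
  at real genome geometry.
- **Seeding**: all randomness descends from one master seed through
  per-purpose `SeedSequence` spawn keys; fixtures are byte-identical for a
  fixed seed and adding a sample never changes existing samples.

What the generator does **not** emulate: spatial correlation of methylation
state between neighbouring CpGs (sites are independent, so window levels
concentrate around 0.7 rather than being bimodal at the window scale),
read-level haplotype structure (per-site counts are independent given the
truth), coverage clustering along amplicons, and methylated→unmethylated
read errors.  Passing recovery tests therefore demonstrate estimator
correctness under the generative model, not robustness to every artifact of
real libraries.  Because sites are independent, site-composition sampling
is the dominant technical-noise source for sparse cells; the noise share of
raw variance is steered by `cell_site_coverage_prob` (≈ 0.95 at coverage
0.2, ≈ 0.65 at coverage 0.7, ≈ 0.15 at full coverage).  The
deep-bulk/shallow-cell fixture used for the noise-share plausibility check
uses coverage 0.7, calibrated so the technical-noise share of raw variance
lands near the published ~53 % share rather than at the sparse-coverage
extreme.

## Problem sizes and numerical choices

Test and acceptance fixtures use one or two chromosomes of 0.4–20 Mb
(≈ 4,000–200,000 CpGs), 1–16 cells, and 5–20 downsampling replicates —
sizes at which every recovery target is resolved to well inside its
tolerance while the whole suite runs in well under a minute of compute per
module.  Degenerate inputs are handled explicitly: empty coverage files
parse to empty tables; zero-depth sites are dropped; windows shorter than
one chromosome clip; an even bulk split has no majority; corrected variance
floors at 0; permutation p never reaches 0 on the Monte-Carlo path; the
pipeline isolates per-cell failures and records them instead of aborting.
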