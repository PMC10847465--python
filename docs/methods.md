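# Methods

This note documents the models and numerical choices behind `scmetseq`:
what each stage computes, the parameters that matter, what the synthetic
data generator does and does not emulate, and the known limitations.

## Bin grid

Copy-number profiles live on a fixed grid of ~500 kb bins over the 22
human autosomes (sex chromosomes are excluded so that burden denominators
always refer to the autosomal genome; the shipped hg19 table totals
2,881,033,286 bp, 5,754 bins at the default width). Each chromosome of
length L receives `floor(L / target_width)` bins; the division remainder
is spread one base at a time over the leading bins, so the tiling covers
the chromosome exactly and every width stays within ±50% of the target.
We chose deterministic equal-width tiling over mappability-scaled bins
because it needs nothing beyond a chromosome-sizes table; sub-width
terminal bins are merged rather than emitted (logged at grid build time).

Reads are assigned to the bin containing their leftmost mapped base —
not the midpoint — the simplest well-defined contract at 0.2× depth where
a 100–150 bp read essentially never spans a 500 kb bin boundary.
Duplicates, secondary/supplementary alignments and reads below MAPQ 30
(configurable) are dropped. GC per bin counts G/C over A/C/G/T ignoring
N; bins with >50% N are masked from normalization.

## Per-cell profiling

**GC normalization.** A lowess curve of count vs. GC (span 0.3) captures
the multiplicative amplification bias; each bin is rescaled by
(global mean / fitted value), with the fitted value floored at 5% of the
mean so near-empty GC strata cannot explode the correction. Masked bins
pass through unchanged.

**Ratios.** Bin ratios divide by the sample mean bin count, so they
average exactly 1; log₂ ratios use a 0.5-read pseudocount floor for
zero-count bins (flagged), keeping the series finite for segmentation.

**MAPD.** Noise is quantified as the median of |log₂r_{b+1} − log₂r_b|
over adjacent bins *within* chromosomes. Although the statistic's name
expands to "mean absolute pairwise difference", the established form is
the median, which is what we compute by default — the median is robust to
the genuine jumps at CNA breakpoints, which is the point of the statistic;
a config switch (`mapd_statistic="mean"`) gives the literal mean form.
Whether the statistic is taken on ratios or log₂ ratios is a free choice;
we use log₂ (standard) and make it the documented contract. Cells pass QC
iff MAPD ≤ 0.45 (at 500 kb bins) and an externally supplied QC-PCR flag,
when present, is not negative.

**Segmentation.** Circular binary segmentation, per chromosome: the arc
(i, j) maximizing the two-sample t statistic between arc and complement
is tested against a permutation null; the split is accepted iff the
permutation p-value (add-one estimator, default 10,000 draws, seeded) is
below α = 10⁻⁴, and the recursion continues on the resulting
sub-segments. Two numerical shortcuts keep this tractable without
changing decisions: (1) a Bonferroni-style union bound over all tested
arcs — when even this conservative upper bound on the p-value clears α
the permutations cannot disagree in the rejecting direction, so the split
is accepted directly; (2) curtailment — with α·B ≈ 1, a single permuted
exceedance already makes significance unreachable, so sampling stops at
the first exceedance (null segments terminate after a handful of draws).
Arcs leaving fewer than 2 bins on either side are not tested. Accepted
breakpoints are then pruned: a cut is undone while removing it increases
the residual sum of squares by less than 5% of the current total
(`prune = 0.05`), iterating from the weakest cut.

**Diploid anchoring.** Instead of a hidden-Markov ploidy caller, segment
mean ratios are clustered in one dimension (sorted greedy merge at 15%
relative distance — half the 50% spacing between adjacent copy-number
levels at diploid anchor); the cluster covering the greatest genomic
length is declared diploid, and its length-weighted mean ratio maps to
copy number 2. This is deterministic, dependency-free, and equivalent to
an HMM baseline for the near-diploid cells the assay cares about; it can
mis-anchor a genome-doubled tumor (see Limitations). Each segment gets
`round(2·ratio/anchor)` copies, floored at 0; log₂ guard cutoffs
(±0.25 by default) pull borderline calls back to neutral — note that with
the default cutoffs the integer rounding is already the stricter
criterion, so the guards only bite when configured more conservatively.
An anchor cluster covering <10% of the genome flags the profile as having
no confident diploid baseline.

**Burden.** CNA burden is the summed length of non-neutral segments
divided by the autosomal genome length. "Detectable CNAs" means burden
strictly greater than 0.02; a burden of exactly 0.02 is not detectable.

## sCTC calling

Ascites: the HK2-high threshold is mean + 5·SD (population SD, ≥20
reference cells required) of HK2 among CK⁻ cells (CK < 400 a.u.); a cell
is flagged iff HK2 ≥ threshold, CK ≥ 400 (the positive cut defaults to
the same 400 a.u. as the negative gate), DAPI⁺ and — by default — CD45⁻.
The CD45⁻ gate is the stricter of the two published phenotype wordings
and is configurable. Blood: the combined single-channel HK2+CK signal is
thresholded at mean + 5·SD of CD45⁺ leukocytes; flagged cells must be
CD45⁻ and DAPI⁺; the summed-intensity interpretation follows the
single-color staining of the two markers. The CD45 positivity split
defaults to an Otsu threshold of the channel when no cut is configured.
All threshold comparisons are inclusive (≥). Density is flagged cells
per ml.

## Decision rule

A sample is positive iff (density ≥ 2.0/ml for ascites, ≥ 3.0/ml for
blood — inclusive) and at least one pair of QC-passing profiles with
burden > 0.02 correlates at r ≥ 0.8 (Pearson, per-bin log₂ ratios).
The failure reason records the first failing branch in the order count
threshold → detectable CNA → concordant pair. The 0.8 cut is our choice:
no published cut exists, within-patient CTC correlations are reported
above 0.91 while unrelated profiles correlate near 0, so 0.8 separates
the regimes with margin on both sides; the CLI reports when moving the
cut across 0.7–0.9 would change a call. Bin-level log₂ ratios are the
default correlation signal (richer at 0.2× than segment means;
segment-level is available). Concordance by correlation threshold is a
proxy for whatever expert review may have contributed in practice.

## Synthetic data

The generator emulates the study conditions so the pipeline can be
exercised end to end:

* **Clonal truths**: non-overlapping gain/loss events (CN ∈ {0,1,3,4,5}),
  sizes uniform 10–40 Mb — the chromosome-arm scale of clonal CNAs —
  placed until the realized burden is within 10% relative of target.
  Tumor cells of a sample share one truth; burdens draw from 0.15–0.5.
* **Counts**: expected bin counts ∝ width × (CN/2) × g(GC) normalized to
  `0.2 × genome / read length` total reads; draws are gamma-Poisson.
  Dispersion 0.01 (default) emulates passing-quality amplification:
  MAPD ≈ 0.15 and within-clone bin-level correlations ≈ 0.9, the regime
  reported for genuine CTCs; the noisy preset (0.2) gives MAPD ≈ 0.65,
  failing the 0.45 gate. g(GC) is a mild log-quadratic bias. The
  synthetic GC track is a deterministic ~5 Mb-period curve; the short
  (isochore-scale) period matters, because a track that varies slowly
  relative to chromosome length would let a single CNA event dominate a
  GC stratum and be absorbed by the lowess fit.
* **Fluids**: intensity tables with CD45⁺ leukocytes, CK⁺ benign
  epithelial cells (ascites), and bright tumor or false-positive cells.
  Malignant sCTC densities are lognormal with median 5.8/ml and IQR
  2.5–11.5/ml (σ = 1.131 matched to that IQR); benign bright-cell counts
  are Poisson with mean 1.2 per 10 ml sample (median 0.1/ml, 25th
  percentile 0, matching a distribution with a point mass at zero).
  Sporadic events in benign cells (rate 0.15) span 0.3–1.2% of the
  autosome, keeping benign burden below the 0.02 threshold and placing
  events at random, hence non-recurrent, positions. Background cell
  composition of benign fluids is not quantified anywhere; these defaults
  are documented constants, not claims about any cohort.

What the generator does **not** emulate: sequence-level amplification
chemistry, read-level artifacts (FASTQ/alignment are upstream of this
package), mappability structure, tumor subclones, and cell-segmentation
errors in imaging. Passing tests therefore demonstrate the pipeline's
correctness under the stated statistical model, not performance on any
particular instrument's data.

## Problem sizes

The test suite runs most simulations on a 100-bin toy genome (2
chromosomes × 50 × 500 kb) and reserves the full 5,754-bin hg19-sized
grid for the burden-recovery check (4 burden levels × 20 cells at 0.2×).
The acceptance script's synthetic cohorts (20/20 and 71/32 samples) use
the toy grid; these sizes were chosen as the smallest at which the
cohort-level statistics are stable.

## Limitations

* Diploid anchoring by majority genomic length mis-scales genomes in
  which less than half the autosome is at the modal ploidy (e.g. after
  whole-genome doubling); such profiles carry the low-confidence flag.
* The permutation fast-accept uses a t-distribution union bound; for
  heavy-tailed count noise at very small segment sizes it is conservative
  (never anti-conservative), which can only make segmentation miss, not
  hallucinate, breakpoints.
* Confidence intervals on cohort metrics are out of scope (per-patient
  resampling data are not available), as are tissue-of-origin inference
  and driver-mutation detection.
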