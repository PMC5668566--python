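# Methods

## Gradient model and profile quantification

A polysome profile is modelled as absorbance versus a continuous gradient
coordinate (arbitrary units, light to heavy, default span 0–10 sampled at
2000 points), collected into 12 equal-width 1-based fractions emulating
1 mL fraction collection.  The synthetic trace is a linear baseline
(offset 0.05, slope 0.02 absorbance units) plus symmetric Gaussian peaks —
RNP, 40S, 60S, 80S and at least two polysomal peaks — plus additive
Gaussian detector noise.  Peak areas in the ground truth are exact
integrals `amplitude · σ · √(2π)`, valid because default peaks sit several
σ inside the trace span.  An exponential-tail skew option exists but is
off by default; real detector peaks are mildly asymmetric, and the
symmetric default keeps the closed-form truth exact.

Quantification proceeds in four steps, each swappable:

1. **Baseline.**  A line through the median absorbance of the first and
   last 2% of points is subtracted.  This exactly removes the generator's
   baseline model; negative residuals are kept (clamping before averaging
   would rectify noise).  Anchors are configurable for traces whose ends
   are not flat.
2. **Segmentation.**  Local maxima are detected on a Savitzky–Golay
   smoothed copy (window ≈1% of the trace, order 3; detection only — the
   original samples are integrated).  The first four maxima are assigned
   light-to-heavy to RNP/40S/60S/80S; each boundary is the absorbance
   minimum between adjacent assigned peaks, and everything from the valley
   after 80S to the trace end is the polysome region.  The default minimum
   prominence is 2% of the trace's dynamic range.  A valley shallower than
   the prominence raises an ambiguity flag rather than an error.
3. **Integration.**  Trapezoidal AUC per region on the corrected trace;
   negative region totals are clamped to zero with a QC flag, since noisy
   tails routinely dip below baseline.
4. **FRP.**  `A_poly / (A_poly + A_80S)`.  The denominator deliberately
   excludes RNP/40S/60S.  A polysome/monosome ratio variant is provided
   but not used by any default path.  Both areas zero is an explicit
   error, not NaN.

Accuracy: on noiseless defaults the estimate is within 5·10⁻⁴ of truth;
across the cohort FRP range (≈0.55–0.75) within 0.005.  The dominant error
term is tail spillover across the 80S/polysome valley, which grows as the
first polysome peak shrinks relative to 80S — below FRP ≈ 0.5 the
noiseless error can exceed 0.005.  Correcting that would require peak
deconvolution, which is out of scope by design: the valley boundary is the
documented, reproducible convention.

## Cohorts, phenotype and clustering

Cohort simulation draws each mouse's true FRP from a group normal
(defaults: control 0.75 ± 0.04, affected 0.55 ± 0.06, chosen as plausible
late-symptomatic nervous-tissue values) truncated to (0, 1), rescales the
polysome amplitudes of a base gradient model to realize that FRP exactly,
and generates phenotypes as linear functions of FRP plus noise: weight
`1.5 + 6.0·FRP` g (σ 0.3) and righting time `33 − 38·FRP` s (σ 2), the
latter capped at 30 s after noise to mirror the assay's termination rule.
Group sizes default to the 3–9 replicate range used for tissue profiling;
larger groups need an explicit override.

Relative phenotypes divide each value by the mean of stage-matched
controls.  Group FRP comparisons use Student's t (equal variances);
one-tailed tests must be requested explicitly and test the first group
greater than the second.  Correlations report Pearson r and Spearman ρ
with test p-values (asymptotic t approximation for Spearman, the scipy
convention).

Clustering standardizes each variable to zero mean and unit SD, computes
Euclidean distances, and agglomerates with the **Ward.D** update — the
Lance–Williams Ward recurrence applied to *unsquared* distances.  This is
intentional: the textbook Ward criterion (Ward.D2) squares distances
first, and scipy's `linkage(..., "ward")` implements only that variant, so
the Ward.D rule is implemented directly (O(n³), fine for cohort sizes;
ties break deterministically by cluster id).  The tests pin the tree to an
independent R `hclust(method="ward.D")` run and to a brute-force recursive
oracle.

## Co-sedimentation

Because blot exposure varies between membranes, all statements are made on
per-lane normalized shares (each protein-sample lane sums to 1).  The
association index is the summed share over a target region's fractions;
the default 12-fraction map assigns fractions 1–2 to RNP, 3 to 40S, 4 to
60S, 5–6 to 80S and 7–12 to polysomes.  Shift statistics between
conditions are the difference in association index and in the
signal-weighted mean fraction index (center of mass); negative means
toward lighter fractions.  Fraction index, not sucrose percentage, is the
reporting unit because fractions are what blots are run from.  Lane noise
in the generator is multiplicative lognormal (unit mean), keeping
intensities nonnegative.

## Translation efficiency

Counts are emulated as negative binomial with shared dispersion (the field
standard for count data; the original quantification used FPKM, so no
count model was prescribed).  Total-RNA means are shared across groups;
planted TE shifts scale the case group's polysomal mean by `2^log2ΔTE`.

`log2TE = log2((POL + c)/(TOT + c))` on CPM (or length-scaled, FPKM-like)
values with pseudo-count c = 0.5 normalized units — enough to avoid
infinite ratios at zero counts with negligible bias at moderate depth.
CPM makes log2TE invariant to per-sample library scaling.

Differential TE uses a paired label-permutation test: the statistic is the
difference of group-mean log2TE per gene; sample labels are permuted once
and applied jointly to both compartments (log2TE is already the paired
contrast, so pairing is automatically preserved).  When the number of
distinct label assignments is ≤ 10,000 they are enumerated exactly and the
p-value is the exact permutation p (identity included); otherwise random
permutations with an add-one correction.  BH FDR is computed across genes,
and raw p < 0.05 selection is also exposed since that is the conventional
reporting threshold for this assay.  This test is a deliberately simple,
clearly labelled substitute for specialised differential-TE tools: it is
comparable in direction and ranking, not in exact p-values.  Note the
discreteness: with 4 vs 4 samples the smallest two-sided p is 2/70, so
α = 0.05 is only barely resolvable; 5–6 per group gives a usable grid.

qPCR: technical replicates are averaged per (gene, sample, compartment);
ΔCt subtracts the arithmetic mean of the two reference-gene Cts (which
equals normalizing expression by the geometric mean of the references);
ΔΔCt is the case-minus-control difference of group-mean ΔCt, and
FC = 2^(−ΔΔCt).  `log2ΔTE = log2 FC_POL − log2 FC_TOT` is the primary
definition (a log-scale difference of fold changes); a raw-difference
variant is provided for comparison because the phrase "difference between
the fold changes" is ambiguous.  On noiseless Ct tables the whole pathway
returns planted values to machine precision.

## Cell-level effect sizes

Percent decrease is defined on arithmetic means of raw (not log)
intensities, matching how mean fluorescence is reported.  For per-cell
data both units of analysis are always computed: pooled cells (default
headline, matching how per-cell ns are reported) and per-preparation
replicate means, acknowledging that pooled cells overstate the effective
sample size.  Axonal ribosome density is count/area per axon profile;
the generator draws Poisson counts over lognormal areas, under which the
per-axon density mean is an unbiased estimator of the true density.
The background-control check declares a treated intensity distribution
"at background" when a two-sample t test fails to reject at a configurable
α (default 0.05).

## Pipeline and reproducibility

All generators take a single integer seed and are byte-reproducible.  The
pipeline fans one global seed out as seed + stage-index so stages can be
re-run in isolation; the manifest records every artifact with a sha256
checksum, and two runs with the same config produce identical checksums.
Formats are plain text throughout (TSV tables, YAML configs, JSON
manifests).

## What the synthetic data does and does not show

The generators emulate the *structure* of the study's inputs — peak
layout, fraction counts, replicate sizes, noise scales — with analytically
known truth, so tests measure estimator correctness, calibration (type-I
error of the t and permutation tests) and effect-size recovery at the
published sample sizes.  They do not emulate detector drift or asymmetric
peak shapes, blot saturation, amplification-efficiency differences between
qPCR primers, cell-segmentation error, or any biological covariance
structure beyond the modelled couplings.  Passing tests therefore
demonstrate that the estimators are correct and calibrated under the
stated models, not that the original tissue-level values (tissue FRP
levels, transcript counts with altered TE, DEG overlaps, qPCR–sequencing
concordance) are reproduced — those depend on unreleased animal data.

## Problem sizes used by the test suite

Type-I calibration uses 1000 null genes (6 vs 6 samples, exhaustive
924-assignment permutation) and 1000 null t-test replicates; effect-size
recovery averages three seeds at the published per-group ns; Monte-Carlo
recovery checks use 20–200 seeds of small cohorts.  These sizes keep the
binomial error on empirical rates comfortably inside the asserted bands.
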