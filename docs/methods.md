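# Methods

## Quantification model

A sample is a five-plane stack: DAPI, pan-keratins, vimentin, PD-L1
(arbitrary fluorescence units, nonnegative) and a binary CD45 mask.  The
CD45 readout in the underlying assay is an immunocytochemistry stain
whose only analytic role is leukocyte exclusion, so it is modeled as a
positivity mask rather than a chromogen image; no brightfield color
processing is attempted.

Per-cell measurement proceeds in four steps.

1. **Nuclear segmentation.**  Otsu threshold on the (optionally
   Gaussian-smoothed, `smoothing_sigma = 1 px`) DAPI plane, then a
   distance-transform watershed seeded at local maxima at least
   `min_peak_distance` (default 5 px ≈ one nucleus radius) apart, then
   an area filter (`min_area_px = 20`, `max_area_px = 10000`).  Otsu was
   chosen because it is parameter-free and exact on the synthetic
   scenes; a blank DAPI plane yields zero cells with a warning rather
   than an error.
2. **Cell regions.**  Each nucleus grows by `dilation_px` (default 6 px,
   intended to cover the cytoplasmic annulus: cell radius − nucleus
   radius + segmentation slack) without crossing another cell's
   territory; contested pixels go to the nearest nucleus.  Ties in that
   distance are resolved deterministically by the distance transform's
   nearest-feature choice; exact ties form a measure-zero pixel set and
   do not affect any quantity tested.  Whether whole-cell or
   nucleus-plus-cytoplasm regions better match manual region-of-interest
   practice is not decidable from first principles; whole-cell regions
   were chosen because all three markers of interest are cytoplasmic or
   membranous.
3. **Background.**  Mean intensity per channel over pixels outside all
   cell regions plus a 2-px guard band (blurred cell rims would
   otherwise inflate it).  At least 100 background pixels are required;
   fewer is an error naming the offending channels.  Manual workflows
   typically use hand-drawn background regions; a global outside-cells
   mean is the deterministic, reproducible analogue and is configurable.
4. **CTCF.**  `integrated density − area × mean background` per channel.
   Negative values are preserved: a cell dimmer than the background is
   informative (keratin-negative), and clipping would bias ratios.

Invariants verified by the test suite: the CTCF identity is recomputable
from every emitted record; integrated densities equal brute-force pixel
sums; scaling a channel by *s* scales its CTCF by exactly *s*; on
noiseless, blur-free scenes CTCF equals the planted intensity to
floating-point precision (~1e-12 relative).

## Calibration and classification

Reference ranges are the empirical min/max of ≥ 100 cells per line
(`min_reference_n = 100`); a robust `[1%, 99%]`-quantile mode exists but
is off by default because the published convention is min/max.  The EMT
threshold is *defined* as the mesenchymal range's lower bound (default
0.88) and the PD-L1 threshold as the epithelial range's upper bound
(default 40); both are dataclass properties so they cannot drift from
the ranges.  Overlapping reference ranges warn rather than error — the
default ranges themselves leave structural gaps (vim/ker 0.28–0.88,
PD-L1 40–60).

A CTC is DAPI⁺ ∧ keratin CTCF > cutoff ∧ CD45⁻.  No numeric keratin
cutoff is published, so the default is self-calibrating: the 99th
percentile of keratin CTCF among the sample's own CD45⁺ cells (a
built-in negative-control population), floored at zero, with a constant
override available.  EMT: ratio = vim CTCF / ker CTCF, eCTC when
ratio ≤ threshold, mCTC above; negative vimentin CTCF clamps the ratio
to 0.  PD-L1: negative/low up to the threshold, positive above.  Values
in the inter-range gap (40, 60) are called positive under the strict
greater-than reading but carry a `pdl1_gap_flag` for sensitivity
analysis, and values above the mesenchymal range (> 350) are also called
positive — both readings of an ambiguous rule, resolved in favor of the
simple threshold and flagged rather than hidden.

Clusters are connected components of the touching graph over CTCs only
(masks dilated by `adjacency_px = 2` intersect, or centroids within a
supplied distance in the image-free path); components of ≥ 2 cells are
clusters, everything else a single.  Mesenchymal predominance uses ≥ 50%
(the boundary counts as predominant).  Low/high-quartile strata of the
vim/ker distribution are computed over the whole analysis set (not per
patient — too few cells per patient), with linear-interpolation
quartiles; LQ is ratio ≤ Q1 and HQ is ratio ≥ Q3, degenerate Q1 = Q3
cases tie-break to MID with a warning, and < 4 cells yield no strata.

## Survival statistics

Conventions deliberately mirror common clinical-statistics software
defaults: Cox regression handles ties by Breslow (Efron switchable),
Wilcoxon drops zero differences (Pratt optional), chi-square applies no
continuity correction (Yates flag available), all tests are two-sided,
and no multiplicity adjustment is applied — the report counts the tests
performed so users can adjust post hoc.  The Wilcoxon test uses the
exact null distribution for ≤ 25 untied nonzero pairs and the
tie-corrected normal approximation otherwise.  Kaplan–Meier medians are
the smallest time with S(t) ≤ 0.5 (infinite when never reached), with
confidence intervals by inverting the survival-function confidence band
(a Brookmeyer–Crowley-type construction) and Greenwood's formula for the
variance of S(t).  Kaplan–Meier and log-rank are computed via lifelines
and Cox via statsmodels' partial-likelihood Newton optimizer; the test
suite cross-checks them against independent oracles (hand product-limit
computation, a direct hypergeometric-moment log-rank implementation,
brute-force maximization of the explicitly enumerated partial
likelihood, and the classical log-rank/Cox-score-test equivalence).
Convergence is verified from the score norm; suspected monotone
likelihood (complete separation: |β| > 15 or SE > 100) flags the fit
rather than failing, and cohort-level analyses skip unfittable
covariates with a logged note, which matters for small cohorts.

## Synthetic data

The generator emulates the study's three populations on a cytospin:
epithelial-like CTCs, mesenchymal-like CTCs and PBMC distractors.  Cells
are disks (nucleus radius 5 px, cell radius 9 px at the default scale)
painted with uniform per-pixel intensity so the planted integrated
intensity is exact; DAPI on the nucleus, markers on the whole cell.  The
forward model is background → Gaussian PSF blur → optional Poisson noise
→ additive Gaussian noise → clip at zero.  Cluster members are chained
with centers 1.8 nucleus radii apart so their masks touch after
segmentation, which makes the adjacency rule fire deterministically.
All randomness flows from a single integer seed; identical spec + seed
gives bit-identical output.

Marker levels per class: keratin and DAPI are log-normal
(median/geometric-SD; no intra-line variance is published, so the
defaults — keratin median 400 for epithelial, 150 for mesenchymal cells,
geometric SD 1.4 — are free choices fixed once in the default model);
vimentin is generated through the vim/ker *ratio*, drawn log-uniformly
over the class's calibration range (0.01–0.28 epithelial, 0.88–22.5
mesenchymal), which pins every generated cell's ratio inside its
reference range by construction; PD-L1 CTCF is log-uniform over 10–40
(epithelial) and 60–350 (mesenchymal).  PBMCs are CD45⁺, essentially
keratin-negative (median 0.5), and vimentin/PD-L1-expressing.

Cohorts draw binary covariates from configured prevalences and event
times by inverting the cumulative hazard of an exponential or Weibull
baseline under proportional hazards.  Random censoring is exponential
with its rate solved numerically so the realized censoring fraction
matches the requested one given the drawn covariates, plus
administrative censoring at the follow-up horizon (60 months default).
The demo pipeline couples outcomes to the *measured* profiles: survival
times are drawn conditional on each synthetic patient's detected
subpopulation flags (log HR 1.638 ≈ ln 5.145 on cluster-mCTC presence,
baseline 0.06/month for OS and 0.25/month for PFS, 30% censoring).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: spatially varying illumination and PSF,
staining chemistry and batch effects, partial-EMT intensity continua
straddling the reference ranges, nuclear morphology variation,
out-of-focus planes, and cohort-level correlation structure beyond the
configured flags.  Classification recovery being 100% on synthetic
scenes reflects that the generated classes sit strictly inside the
calibration ranges; real CTCs in the inter-range gaps are exactly the
cases the gap flag exists for.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their statistical
tolerances meaningful while keeping the suite fast: parameter recovery
at n ∈ {100, 500} patients; hazard-ratio recovery with 50 replicates of
n = 500 (median HR within ±20% of 5.145, ≥ 90% CI coverage); log-rank
null calibration with 1000 replicates of n = 60 against the binomial
95% band around 0.05; the end-to-end image test plants 400 cells
(100 + 100 CTCs, 200 PBMCs) on a 1280² noiseless field.  Exact
quantities (thresholds, CTCF identities) are asserted at
floating-point precision; Monte-Carlo medians use 5–6% relative
tolerance.  Coordinates are 0-based with x = column, y = row; masks use
half-open pixel semantics; all CSV output is UTF-8 with `NA` for
missing values.

## Known limitations

Single-plane analysis only (confocal z-series are assumed reduced to one
plane per channel upstream); no illumination-field correction; no
proportional-hazards diagnostics, time-varying covariates or competing
risks; calibration supports exactly two reference lines; the CD45 mask
abstraction cannot detect chromogen bleed-through artifacts.
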