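# Methods

## Problem and model

Tongue diagnosis reads the color of the tongue body as a proxy for systemic
condition. Because some practitioners examine patients sitting and others
supine, the analytical question is whether the posture itself shifts tongue
color enough to matter. The pipeline quantifies color as CIE L\*a\*b\*
(device-independent; L\* lightness 0–100, a\* red–green, b\* yellow–blue),
measures the per-patient sitting→supine change with the CIEDE2000 color
difference ΔE₀₀, and asks two questions: (1) what fraction of patients fall
below a visual-acceptability threshold, and (2) do larger shifts associate
with biometric covariates (blood pressure, glycemia, lipids), which would
point at microcirculatory causes.

## Colorimetry

**sRGB → Lab.** Standard chain: sRGB companding removed (IEC 61966-2-1
piecewise curve), linear RGB → XYZ through the sRGB/D65 primaries matrix,
XYZ → L\*a\*b\* against a reference white. The D65 white point is defined as
the matrix image of RGB (1,1,1), so sRGB white maps exactly to
Lab (100, 0, 0); this differs from the textbook D65 tabulation by < 1e-6.
D50 is available as an alternative white point for the Lab normalization;
no chromatic-adaptation transform is applied. The conversion is validated
against scikit-image's independent implementation to ≤ 0.05 ΔE₀₀ over 1000
random colors.

**CIEDE2000.** Implemented in full, in degrees (the formula's native
units), with the published implementation notes for the edge cases: the
hue-difference terms are zeroed when either primed chroma is zero, and the
mean hue uses the |h₁′ − h₂′| > 180° wraparound rules. Signed components are
sample − reference; the pipeline fixes sitting = reference, supine = sample,
so ΔL′ < 0 means the tongue darkens when supine. Parametric coefficients
default to kL = kC = kH = 1. Correctness is pinned by the standard 34-pair
verification set (agreement ≤ 1e-4, which exercises the known hue-mean
pitfalls), by exact agreement with scikit-image on random pairs, and by the
closed form ΔE₀₀ = |ΔL|/(kL·S_L) for achromatic pairs (≤ 1e-10).

Internally everything is carried in full double precision; report tables
round ΔE₀₀ to one decimal and components to two, matching how such tables
are conventionally printed.

## Segmentation and region partition

Tongue extraction is a deliberately simple, deterministic chromaticity rule:
a pixel is tongue if its Lab a\* exceeds a threshold (default 12; tongue
tissue sits near a\* ≈ 20–35, neutral backgrounds near 0) and its lightness
exceeds a floor (default 5, rejecting near-black pixels with unstable
chromaticity). The largest 8-connected component is kept and holes are
filled. This assumes evenly lit, gloss-free images, which is what
integrating-sphere tongue rigs produce and what the synthetic generator
renders; it is not a general-purpose tongue segmenter for consumer photos.
Precomputed masks can be supplied instead.

The mask is partitioned into four regions by ratios of the tongue shape,
with the image upright (root at top, apex at bottom):

- **posterior** — mask pixels in the top `posterior_fraction` (default 0.20)
  of the mask bounding-box height;
- **apex** — the bottom `apex_fraction` (default 0.20);
- **edge** — within the remaining rows, the outermost
  `edge_band_fraction` (default 0.15) of each row's tongue run, both sides;
- **middle** — the rest.

The edge band is defined per row relative to that row's width rather than as
a fixed band on the bounding box, so it follows the tongue outline. The
division ratios of the underlying published partition scheme exist only as a
drawing, so these defaults are provisional by construction; they are
mandatory configuration in the API sense that every report serializes the
ratios actually used. The partition is exact: every mask pixel gets exactly
one region label, which the test suite checks by brute-force pixel counting
on random masks.

Region color is the arithmetic per-channel mean of the region's pixel-wise
Lab values (median available as an option). The edge region feeds the
headline analysis because it is least affected by tongue coating; other
regions are computed but not classified by default.

## Position comparison

Per patient, ΔE₀₀ between the edge colors. Classification uses a strict
inequality — acceptable iff ΔE₀₀ < AT — with AT = 4.1, the 50:50%
acceptability threshold from gingival-color studies, as default
(alternatives 4.0 and 2.8 are configurable; a perceptibility threshold PT
can be set but has no default). The strictness matters at the boundary: a
patient printing exactly 4.1 is counted in the non-acceptable group. Cohort
summaries report the arithmetic mean, the even-n median (mean of the two
central order statistics), and the acceptable proportion.

## Associations and reference flags

Numeric covariates (age, BMI, SBP, DBP, TG, HDL-C, LDL-C, HbA1c, FPG) are
related to ΔE₀₀ with the sample Pearson correlation, two-sided p from the t
transform with n−2 df. Categorical covariates (sex, smoking, cardiovascular
drug use) use the correlation ratio η² = SS_between / SS_total with p from
the one-way ANOVA F statistic; for binary groupings η² equals the squared
point-biserial correlation, which the tests verify. Missing values are
deleted pairwise per covariate and the n used is reported. No
multiple-testing correction is applied — the report mirrors conventional
single-table presentation and should be read accordingly.

Reference flags mark laboratory items at prompt-consultation level:
blood pressure (SBP ≥ 160 mmHg or DBP ≥ 100 mmHg, one item even if both
exceed), TG ≥ 500 mg/dL, FPG ≥ 126 mg/dL, HbA1c ≥ 6.5%, and LDL-C ≥ 180
mg/dL. The LDL-C item (high-risk dyslipidemia consultation level) is part of
the default set; an HDL-C ≥ 100 mg/dL item is available but off by default.
The criteria set is fully configurable and serialized into reports. The
flag-by-group summary cross-tabulates, per acceptability group, patients
with ≤ 1 versus ≥ 2 flagged items.

Association results carry their sign, but downstream checks in this package
compare magnitudes: the example cohort's published association table prints
negative r for SBP/HbA1c/FPG while recomputation from the same tables gives
positive values of identical magnitude (and the accompanying narrative
describes the correlations as positive), so the magnitude is the
reproducible quantity.

## Synthetic data generator

The generator emulates what a calibrated integrating-sphere tongue camera
delivers: evenly illuminated, gloss-free, fixed-geometry images. A tongue is
a vertically elongated superellipse (default 200×150 frame, exponent 2.5)
on a dark neutral background; each region is painted with its Lab color plus
independent Gaussian noise per channel (default σ = 2), converted to sRGB
per pixel with gamut clipping.

Default cohort conditions mirror the 18-patient study setting: sitting edge
baseline (42.9, 27.1, 5.3) with between-patient scatter (4.3, 3.2, 2.7) per
channel — the observed means and SDs of the example cohort's sitting
column — paler, less chromatic defaults for posterior/middle/apex; true
shift magnitudes lognormal with median 2.34 ΔE₀₀ and log-sd 0.73, chosen so
that the probability of exceeding the 4.1 threshold is ≈ 4/18, matching the
observed split. Shift directions are uniform on the Lab unit sphere, with an
optional lightness bias (the largest observed shifts are ΔL′-dominated); the
real direction distribution is unknown, so bias is a parameter, not an
assertion.

Because the analysis measures shifts in ΔE₀₀, the generator's dial is also
ΔE₀₀: a drawn magnitude is realized by scaling the random direction with
bracketed Brent root-finding (tolerance 1e-10) until the CIEDE2000 distance
from the sitting color equals the target, then applying the same Lab
displacement to all regions. Baseline scatter and shift direction are
resampled (up to 64 draws) if a draw leaves the sRGB gamut; a shift that
fits in no direction raises a gamut error for that patient. Biometric tables
are drawn from plausible elderly-outpatient marginals; when an association
is configured, the chosen covariate is intercept + slope·(true ΔE₀₀) +
Gaussian noise, and `slope_for_target_r` converts a desired population r
into the slope.

All randomness flows from a single integer seed through one generator;
identical spec + seed reproduces every artifact bit for bit.

**What passing synthetic tests does and does not show.** The generator
reproduces the measurement chain (known colors → pixels → segmentation →
region means → ΔE₀₀) and the statistical structure (shift distribution,
covariate association), so it validates the pipeline's numerics end to end:
with σ = 2 noise and ≥ 2000 edge pixels, recovered ΔE₀₀ is within 0.2 of
truth in ≥ 95% of replicates, and an injected r = 0.55 association at n = 18
is covered by the recovered sampling distribution. It does not render
papillae texture, tongue coating, specular gloss, pose variation or
miscalibration, so passing tests say nothing about segmentation robustness
on uncontrolled photographs.

## Numerical and design choices

- Hue angle of an achromatic color is 0 by convention; a floating-point
  `-0° mod 360 = 360` edge case is folded back to 0.
- Even-n median = mean of the two central order statistics. From one-decimal
  printed inputs this yields 2.35 on the example cohort versus the published
  2.34 computed from unrounded data — the reason cohort checks carry ±0.05.
- Problem sizes in the stochastic tests (e.g. 20 recovery replicates at the
  default 200×150 frame, 200 small-frame cohorts for association recovery)
  are chosen to keep the full suite under half a minute while leaving the
  binomial bounds meaningful.
- Null-association checks use the exact t-based null distribution of r at
  n = 18 (P(|r| < 0.4) = 0.90) with a 3σ binomial allowance, rather than a
  nominal round-number rate.
- CSV interchange: UTF-8, "." decimal separator, Unicode minus (U+2212)
  normalized on read; header matching is case-insensitive with unit
  suffixes ("(mmHg)") ignored.

## Known limitations

- The acceptability threshold 4.1 is borrowed from gingival-color research;
  no tongue-specific AT/PT calibration exists in this package.
- The partition ratios are provisional defaults, not measured constants;
  conclusions that depend on exact region boundaries should vary them.
- The segmenter presumes calibrated, gloss-free imagery (see above).
- Associations are univariable and uncorrected for multiplicity; n = 18-type
  cohorts give wide sampling intervals (±~0.45 on r), so signs and
  significance near the boundary are fragile.
- Time-course effects of sustained supine posture (beyond ~20 minutes) are
  out of scope; the comparison is a single paired measurement per patient.
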