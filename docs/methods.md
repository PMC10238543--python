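# Methods

This note documents the model and procedure choices in `pris`, their
defaults, and what the synthetic experiments do and do not demonstrate.

## Imaging and compartments

Volumes are scalar HU arrays with physical spacing; axial slices are the
first two array axes and all geometry refers to voxel centers. Images
are resampled once, before any compartment construction or feature
extraction, to an isotropic working grid (default 1 mm): linear
interpolation for HU, nearest-neighbor for masks so labels stay binary.
The interpolation scheme is a package convention — imaging protocols
rarely state one — and label-preserving nearest-neighbor is the standard
choice. Dead pixels (non-finite values, or values at/below an optional
HU sentinel) are replaced by the mean of live pixels in their in-slice
9×9 neighborhood before resampling, since non-finite values would poison
linear interpolation; a pixel whose entire neighborhood is dead falls
back to the slice median with a logged warning.

Peritumoral geometry is two-dimensional: head-and-neck planning CT is
acquired with ~3 mm slices, so a 3D "ring" would mix tissue at very
different physical distances. Per slice, the dilation radius in pixels
is `round(15 mm / pixel size)`; rounding of the quotient is a
convention (the formula's source does not specify floor/ceil). The band
is partitioned at one- and two-thirds of that radius via the Euclidean
distance transform from the tumor, which is mathematically identical to
dilating with a disk structuring element but order-independent —
iterated dilations would make the ring boundaries depend on iteration
order. Air (< −900 HU) is excluded from the peritumoral rings only;
intratumoral pixels are kept regardless of HU, because air exclusion is
motivated by the peritumoral tissue microenvironment. Slices with
artifacts can be dropped via an explicit per-slice exclusion list; there
is no automatic artifact detection. Tumors under 200 total voxels are
rejected as too small for stable texture statistics.

## Texture features

All operators are 2D and per-pixel. Convolutional families (Laws,
Gabor, gradients) use full-image context with edge-replicating borders,
so flat surroundings behave like flat tissue rather than a step to
zero. Co-occurrence families (Haralick, CoLlAGe) restrict pixel pairs
to the compartment, so tissue outside a region never enters its counts;
a window that contributes no valid pair degenerates to a point-mass
matrix (energy 1, entropy 0).

* **Laws (25)** — outer products of L5/E5/S5/W5/R5; kernel `AB` applies
  `A` along y and `B` along x. Every kernel with a zero-sum factor
  annihilates constants; L5L5 scales a constant by 256.
* **Gabor (48)** — 6 wavelengths (2, 4, 6, 8, 10, 12 px) × 8
  orientations (0° to 157.5° in 22.5° steps), complex kernels from
  scikit-image, magnitude response. The bank size is pinned to 48; the
  wavelength grid fills the 2–12 px band evenly and the orientation grid
  completes the half-circle at 22.5° resolution. Kernels are made
  zero-DC so that responses are illumination-invariant and exactly
  orientation-invariant on constant regions (discretized Gabor kernels
  otherwise leak a DC component that varies with orientation,
  drastically at the 2 px Nyquist wavelength).
* **Haralick (13)** — per pixel, a symmetric normalized GLCM from
  unit-offset pairs pooled over 0°/45°/90°/135° inside a 5×5 window,
  with 64 gray levels quantized over the compartment's HU range on that
  slice; descriptors: entropy, energy, inertia, inverse difference
  moment, correlation, the two information measures of correlation, and
  the sum/difference average, variance and entropy families. Natural
  logs throughout; sum variance is centered on the sum average (not the
  sum entropy, a known quirk of the original formulation); correlation
  and IMC1 are defined as 0 for degenerate (zero-variance) matrices.
* **CoLlAGe (13)** — x/y gradients via central differences; per pixel
  the principal axis of the windowed gradient second-moment matrix gives
  an orientation modulo 180°, sign-aligned with the windowed mean
  gradient to span [0°, 360°); zero-gradient windows are assigned 0°.
  The orientation image is quantized into 64 bins and passed through the
  same windowed co-occurrence machinery.
* **Intensity (13)** — raw HU; windowed (5×5) mean, median, std, range,
  histogram entropy and energy (32 levels), skewness and kurtosis; x, y
  and combined gradients; Laplacian. The family's composition is a
  package convention chosen so that the full vector's decomposition is
  exact: 13 intensity maps restricted to the intratumoral compartment
  plus 99 texture maps in all four compartments gives
  (4·99 + 13)·5 = 2045 entries.

Aggregation pools per-pixel responses over all tumor-bearing slices of a
compartment and takes mean, median, std, skewness (third standardized
moment, biased) and excess kurtosis (biased); both shape statistics are
defined as 0 for constant pools. An alternative slice-wise mode
(statistic per slice, unweighted average across slices) is available via
`mode="slice_mean"` since the pooling order is genuinely ambiguous in
prose descriptions of such pipelines; pooled-pixels is the default.
Features are z-scored with training-cohort parameters applied unchanged
to validation cohorts; zero-variance training features are dropped.

## Signature

The LASSO-Cox penalty path holds 100 values log-spaced from the
data-determined maximum down to 1 % of it (scikit-survival's Coxnet).
K-fold (default 10) cross-validated Breslow partial-likelihood deviance
nominates a penalty; deviance-minimizing selection is used rather than
a 1-SE rule. The returned model is the path point nearest the nominee
with **exactly** `n_features` (default 7) nonzero coefficients. Because
a discrete path frequently steps over a given count (counts can jump
from 6 to 8 between adjacent grid points), the implementation bisects in
log-penalty between the bracketing path points when the exact count is
absent from the grid; only if no penalty anywhere attains the count does
it raise an error listing the attainable counts. This preserves the
locked-size contract without which the signature definition is unusable
on a large fraction of datasets.

The score is the inner product of the coefficients with the
standardized features. Two cutoffs dichotomize patients (high ⇔ score
strictly above the cutoff): the training median, and the minimum-p
cutoff scanning every unique training score whose split leaves at least
10 % of patients (and 2 events) on each side, taking the split with the
smallest two-group log-rank p (ties resolved toward the smaller
cutoff). The scan uses an in-package vectorized hypergeometric log-rank
over all candidate splits simultaneously; it agrees with per-split
lifelines tests to machine precision. The minimum-p procedure is
intentionally optimistic under the null — its p-values are selection
statistics, not significance levels — which the null-simulation test
documents rather than corrects, matching how such cutoffs are used for
grouping rather than inference.

## Survival statistics

Kaplan–Meier, two-group log-rank, and Cox regression are backed by
lifelines (Efron tie handling, Wald intervals, two-sided tests at
α = 0.05); Harrell's C and the IPCW cumulative/dynamic time-dependent
AUC by scikit-survival. Each operation is validated against an
independently coded small-instance oracle (closed-form products, O(n²)
pair counts with the event-before-censoring tie rule, Newton iteration
on the explicit binary-covariate partial likelihood), so the contracts
do not depend on the backing library. The treatment-benefit interaction
is the Wald test of the product term in a Cox model with both main
effects.

## Nomogram and decision curves

The nomogram maps each covariate's Cox contribution affinely to points,
with 0–100 spanning the widest-effect covariate over the training
cohort; total points map back to survival through the step-function
Breslow baseline, and the points route reproduces the direct Cox
prediction to machine precision. Calibration bins patients by predicted
survival quantiles (default 4 bins), compares bin-mean predictions with
the Kaplan–Meier estimate at the horizon, and forms a
Hosmer–Lemeshow-type chi-square (df = bins − 2); event-free bins merge
into their neighbor. Decision curves use the treated-if-risk-≥-threshold
rule with net benefit TP/N − (FP/N)·pt/(1−pt); "true-positive rate" is
a cohort fraction (TP/N), the only reading under which the treat-all
curve matches its closed form ρ − (1−ρ)·pt/(1−pt). Outcomes at a
horizon under censoring use inverse-probability-of-censoring weights
(censored-before-horizon patients carry weight 0). Model C-indices are
compared by patient-level bootstrap (default 2000 resamples, seeded).

## Synthetic data

Phantoms place an ellipsoidal tumor in ~40 HU soft tissue on an
anisotropic grid (default 0.5 × 0.5 × 3 mm, matching planning-CT
resolution), with stationary Gaussian-random-field texture inside the
tumor (default correlation length 2 mm, contrast 60 HU) and a distinct
coarser field in the peritumoral shell (4 mm, 25 HU), i.i.d. HU noise
(10 HU), optional −1000 HU air boxes and NaN dead pixels; HU is clipped
to [−1024, 3071] and the tumor must leave a full 15 mm in-plane margin.

Cohorts draw standardized features X and survival from a Weibull
proportional-hazards model (default shape 1.5, scale 10 years) with
linear predictor η = Xβ + γ·treat + δ·treat·𝟙[Xβ > median(Xβ)], so a
negative δ plants a chemotherapy benefit confined to the high-risk
stratum — the stratum is defined by the true linear predictor's median,
mirroring the analysis's own median-cutoff logic. Censoring is
independent Uniform(0, c) with c calibrated by bisection to the
requested censored fraction (default 0.3, typical of oncology cohorts
with multi-year follow-up). Clinical covariates (age, gender, subsite,
smoking pack-years, T/N/AJCC stage, recurrence) are drawn from
distributions resembling a stage I–II oropharyngeal population; they are
decorative for the survival mechanics but exercised by the balanced
training-split procedure, which repeatedly samples candidate training
sets, tests selected-vs-remaining balance (rank-sum for continuous,
chi-square for categorical variables at α = 0.05), counts appearances
in balanced iterations, and returns the top-k patients by count (ties
by patient id).

What the synthetics do **not** emulate: real anatomy, scanner/protocol
effects, contrast phases, inter-observer segmentation variability, or
correlated feature noise. Passing tests therefore demonstrate the
correctness and statistical calibration of the machinery — not clinical
performance on patient data, whose headline hazard ratios and C-indices
depend on cohorts this package does not ship.

## Problem sizes and numerical conventions

Simulation-based tests use 100-seed batteries at n = 300–400 for
recovery rates and 200 seeds for null calibration, sizes at which the
checked proportions are stable to a few percent; the demonstration
pipeline and geometry suites use phantoms of ~70–110 mm field of view
with single-to-few tumor slices, large enough for every compartment to
be populated. Quantization uses 64 gray levels (32 for the windowed
intensity histogram); co-occurrence logs are natural; float comparisons
in tests use explicit absolute/relative tolerances stated per test.

## Known limitations

2D-only texture operators (by design, matching the thick-slice
geometry); no IBSI-certified reference values; per-pixel co-occurrence
maps are computed in a Python loop and dominate extraction time
(~2–3 s per phantom patient at demo sizes); the calibration chi-square
uses the common df = bins − 2 approximation; DICOM reading assumes a
single axial series with uniform slice spacing.
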