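# Methods

## Measurement model

The quantity of interest is trunk-muscle composition on a single axial CT
slice through the middle of a vertebral body (mid-T4 or mid-T10), inside a
fascia region of interest (ROI): the compartment enclosed by the
perimuscular deep fascia, i.e. muscle plus intermuscular fat, excluding
subcutaneous fat. Two endpoints are computed from a muscle mask M on the
evaluation slice:

* cross-sectional area A = |M| · s_r · s_c / 100 (cm², with in-plane
  spacing s_r, s_c in mm);
* density D = mean HU over M.

Vertebral-level identification is an input (a slice index), as in manual
practice; automated spine labeling is out of scope. ROIs arrive as boolean
masks or as closed polygons rasterized with a pinned rule: a pixel (r, c)
covers [r, r+1) × [c, c+1), its center (c + 0.5, r + 0.5) is tested against
the polygon under the even-odd (crossing-number) rule. The rule is fixed —
and implemented in-package rather than delegated — because area values must
be bit-reproducible across environments and self-intersecting hand-drawn
contours must have a deterministic interpretation.

## Fixed-threshold segmentation

Muscle = ROI voxels with HU in [−29, 150], minus bone. The window bounds
follow the adult convention: −30…150 HU delimits anatomical muscle and −29
HU separates muscle tissue from fat, so −30 belongs to fat and −29 is the
first muscle value. Bone is never stated operationally in the measurement
convention this package follows, so it is defined here as: connected
components seeded from voxels strictly above 150 HU, hole-filled
(`scipy.ndimage.binary_fill_holes`), so a fat-like marrow cavity inside a
cortical shell is classified bone. The strict inequality keeps the bone
seed disjoint from the muscle window's inclusive upper bound: a voxel at
exactly 150 HU is muscle, not bone.

## Gaussian-mixture segmentation

The HU spectrum of the intrafascial compartment is bimodal: adipose tissue
near −100 HU and the muscle–lipid system near +40 HU. The spectrum is
binned at 1 HU over [−200, 200] (bins centered on integers, so
integer-valued HU data land exactly on centers) and fitted with

f(x) = a_f·exp(−(x−b_f)²/2c_f²) + a_m·exp(−(x−b_m)²/2c_m²)

by damped least squares (Levenberg–Marquardt via
`scipy.optimize.least_squares(method="lm")`) on the (bin center, count)
pairs — curve fitting to the spectrum, not EM on voxels. Initialization:
b_f = spectrum mode below −30 HU, b_m = mode above 0 HU, c_f = c_m = 10 HU,
a_m = peak count above 0 HU, a_f = a_m times the adipose/muscle voxel-count
ratio. Width parameters enter squared, so their fitted sign is normalized;
curves are ordered so the adipose peak lies below the muscle peak.

Thresholds derived from the fit:

* **seed threshold** = b_m, used strictly (seeds are voxels with
  HU > b_m);
* **lower growth threshold** = the HU where the two curves intersect in
  the open interval (b_f, b_m) — the equal-count boundary, the
  image-specific analogue of the universal −29 HU cut — solved in closed
  form from the quadratic obtained by equating log-densities, with
  fallback b_m − 2c_m when no crossing exists between the peaks.

Muscle is then grown in 3-D from the seeds: the maximal set of ROI-slab
voxels reachable through 26-connected paths of voxels with HU ≥ the lower
threshold, computed as connected-component labeling of the thresholded slab
restricted to seed-containing components (equivalent to breadth-first
growth, and monotone in the threshold). The slab is the ROI slice ± 5
slices with the ROI mask propagated unchanged — a finite 3-D neighborhood
that reconciles volumetric growing with single-slice measurement. Bone is
excluded from the histogram, the seeds and the growth domain, i.e. before
growing. Area and density are evaluated on the ROI slice only.

Degenerate spectra (no adipose population, e.g. a phantom without
intermuscular fat) cannot anchor the adipose curve: the fit is refused when
fewer than 3 informative bins lie on either side of −30 HU, where
informative means a count above 0.1% of the spectrum peak (an absolute
nonzero test would be meaningless for synthetic float-valued spectra whose
Gaussian tails never reach zero). The pipeline then falls back to the
fixed-threshold mask and flags the result `gmm_degenerate_fallback_fixed`;
empty masks are returned flagged with area 0 and density NaN rather than
raised, so batch runs degrade per-subject, not globally.

## Statistics

* **Bland–Altman agreement**: differences oriented fixed − GMM; mean
  difference d̄ and sample SD (n−1); 95% limits of agreement d̄ ± 1.96 SD.
  The midpoint of the limits equals d̄ by construction — an identity used
  as a self-check on reported limit pairs.
* **Two-sample t tests**: variance-gated by default — Levene's test
  (mean-centered) at α = 0.05 selects pooled-variance or Welch
  (Satterthwaite df). From printed summaries, where Levene is unavailable,
  the gate is the two-sided F ratio test on the variance ratio. The gate
  matters: of the eight case-control muscle comparisons in the reference
  summaries, the T4 adaptive-model size row is significant under Welch
  (p ≈ 0.026) but not pooled (p ≈ 0.068), and only the gated reading
  reproduces the reported p = 0.03. Both variants remain available
  explicitly.
* **χ² (2×2)**: Pearson, df = 1, no continuity correction. Note the
  reference cohort's sex distribution (15/5 vs 30/10, both 75% male) gives
  χ² = 0, p = 1 exactly; the reported p = 0.63 for that row is not
  reproducible from its own counts and is not emulated.
* **One-way ANOVA** for OI-type subgroups; the two-group case equals the
  pooled t².
* Sample SD uses n−1 throughout; all p two-sided; no multiplicity
  correction (none is applied in the reference analysis). Display
  convention: summaries to 1 decimal, agreement statistics to 2 decimals,
  p to 2 decimals with "< 0.01" below 0.005.
* **Cohort filter**: subjects with any exclusion flag (poor image quality,
  lost images) are removed; a subject with several flags is excluded once
  but listed under every reason, with the multiplicity reported.

## Synthetic data

**Phantoms.** Compartments are 2.5-D shapes (per-slice ellipses, annuli,
boxes extruded over a slab) filled with independent normal HU noise,
rounded to integer HU and clipped to [−1024, 3071]. Defaults emulate a
chest section: muscle N(45, 5) HU as an elliptical ring (~43 cm² at 1 mm
pixels on a 128×128 grid), intermuscular fat N(−100, 15) inside it, and a
cortical annulus N(400, 50) exactly tiling a marrow core N(−60, 20) — the
hardest case for bone subtraction. The fascia ROI ground truth is the
union of the soft-tissue and bone compartments. Overlapping compartments
are rejected, not resolved. Phantom geometry is deliberately sub-patient
scale (a 12×128×128 grid rather than a 512² chest) to keep the validation
suite fast; areas are internally consistent with their own spacing, and
all area checks are relative.

A phantom with muscle pulled toward 22 HU (SD 18) models myosteatosis: the
fixed window clips the muscle lipid tail below −29 HU while the fitted
intersection threshold follows it (typically near −50 HU), so the adaptive
method measures at least as much muscle — the direction expected when
comparing the methods in lipid-rich muscle.

**Cohorts.** Per-group samples are standard-normal draws z-scored and
affinely rescaled, so the sample mean and SD match the requested targets to
machine precision; group summaries of a published table can therefore be
reproduced deterministically from n, mean and SD alone. Variables are
generated independently: between-variable correlations, and any coupling
between a subject's demographics and their image, are *not* modeled —
tests on these cohorts validate the statistical pipeline's arithmetic, not
distributional realism.

**Demo study.** 20 case-like and 40 control-like subjects; demographics
moment-matched to the reference summaries, sex 15/5 and 30/10, OI types
I/III/IV at 15/2/3. Per subject and level a phantom is generated with
muscle mean HU drawn from N(40, 5) (cases) or N(48, 4.5) (controls) and
in-plane scale 0.92/1.00 × N(1, 0.04), T10 scaled by 0.72 — effect sizes
chosen to echo the case-control density deficit at phantom scale. One
global seed is fanned out through `numpy.random.SeedSequence` substreams,
so the manifest seed fully determines every output byte.

What phantom validation does not show: performance on real anatomy
(partial-volume effects at fascia boundaries, beam hardening,
reconstruction-kernel texture, contact between muscle groups), HU
calibration drift, or manual-contour variability. The phantoms establish
correctness of the algorithms under their own model assumptions.

## Numerical choices and edge cases

* Histogram: 1 HU bins over [−200, 200]; out-of-range voxels excluded;
  an all-out-of-range ROI is an error.
* Fit failure (optimizer status ≤ 0) raises with the last iterate
  attached; collapsed configurations (non-separated peaks, non-positive
  widths) are reported degenerate.
* Region growing requires seeds inside the ROI slab; empty seed sets are
  an error at the primitive level but an empty *grown* mask is a flagged
  result.
* DICOM I/O stores HU via RescaleSlope 1 / RescaleIntercept −1024 as
  unsigned 16-bit; slices are ordered by ImagePositionPatient z, never by
  file name; mixed SeriesInstanceUIDs are rejected. NIfTI volumes store
  int16 HU with spacing in the header; round trips are bit-identical.
* Levene's statistic on a zero-within-spread group divides by zero by
  construction; the gate treats the resulting p as decisive (0) or, for
  fully degenerate all-equal input, defaults to pooled (p = 1).

## Known limitations

* Single-slice endpoints only; no volumetric muscle measurement.
* No automatic fascia delineation or individual-muscle labeling; the ROI
  defines the muscle-group composition.
* The two-Gaussian model assumes exactly two populations inside the
  fascia; a third population (e.g. contrast-enhanced vessels) would bias
  the fit and is not modeled.
* No multi-scanner HU harmonization; thresholds adapt per image but
  systematic calibration offsets propagate into density values.
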