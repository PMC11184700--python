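# trunkcomp

Trunk-muscle body composition from chest CT, for researchers studying
muscle quantity and quality in pediatric bone disease — in particular
children with osteogenesis imperfecta (OI) scanned opportunistically with
low-dose chest CT.

On a single axial slice through the mid-T4 or mid-T10 vertebral body, the
package measures two endpoints inside a fascia region of interest (the
compartment enclosed by the perimuscular deep fascia):

* **muscle size** — cross-sectional area, cm²;
* **muscle density** — mean attenuation in Hounsfield Units (HU), a proxy
  for muscle quality that falls as intramuscular fat rises (myosteatosis).

Two segmentation methods are implemented and can be compared head-to-head:

1. **Fixed thresholds.** Muscle is any ROI voxel in the adult anatomical
   window, with the fat/muscle cut at −29 HU (so muscle = HU ∈ [−29, 150]),
   after subtracting bone. Bone is delineated as hole-filled connected
   components seeded from voxels above 150 HU, so fat-like marrow inside a
   cortical shell is removed along with the shell.
2. **Gaussian-mixture thresholds.** The HU spectrum of the intrafascial
   compartment is fitted with a sum of two Gaussian curves,

   *f*(x) = a_f · exp(−(x−b_f)²/2c_f²) + a_m · exp(−(x−b_m)²/2c_m²),

   (adipose and muscle populations) by Levenberg–Marquardt damped least
   squares. Voxels brighter than the muscle peak b_m seed a 26-connected 3-D
   region growing constrained to the ROI slab; growth admits voxels down to
   the HU where the two fitted curves intersect — an image-specific
   fat/muscle boundary that adapts to the subject's own fat content and
   scanner calibration, which matters in children.

The statistics layer provides Bland–Altman limits of agreement between the
two methods (mean difference ± 1.96 SD, oriented fixed − GMM), variance-gated
two-sample t tests (Levene at α = 0.05 choosing pooled vs. Welch), χ² tests,
one-way ANOVA, a cohort exclusion filter, and builders for the full table
set of a case-control analysis.

Because raw patient volumes cannot be redistributed, the package ships a
phantom generator: synthetic chest cross-sections with muscle (N(45, 5) HU),
intermuscular fat (N(−100, 15) HU), a cortical-bone annulus with fat-like
marrow, and analytically known compartment masks and areas — plus a cohort
generator that reproduces requested per-group (mean, SD, n) summaries
exactly. Every stage is validated against this ground truth.

## Worked example

```python
import trunkcomp as tc

spec = tc.chest_phantom_spec(noise_seed=7)       # muscle N(45,5), fat N(-100,15)
volume, truth = tc.generate_phantom(spec)
roi = truth.fascia_roi

fixed = tc.segment_fixed_threshold(volume.voxels[roi.slice_index], roi, (1.0, 1.0))
gmm = tc.segment_gmm(volume, roi)

print(f"truth: {truth.true_area_cm2['muscle']:.2f} cm^2 of muscle at 45 HU")
print(f"fixed: {fixed.area_cm2:.2f} cm^2, {fixed.density_hu:.1f} HU")
print(f"gmm:   {gmm.area_cm2:.2f} cm^2, {gmm.density_hu:.1f} HU "
      f"(muscle peak {gmm.fit.muscle.peak:.1f} HU, "
      f"growth threshold {gmm.fit.lower_growth_threshold:.1f} HU)")
```

prints

```
truth: 43.00 cm^2 of muscle at 45 HU
fixed: 43.00 cm^2, 45.1 HU
gmm:   43.00 cm^2, 45.1 HU (muscle peak 45.0 HU, growth threshold 7.1 HU)
```

Both methods recover the true ring area exactly and the mean density to
0.1 HU; the mixture fit locates the muscle peak at 45.0 HU and places the
image-specific fat/muscle boundary at 7.1 HU, where the two fitted curves
cross. On phantoms with lipid-rich muscle (mean pulled toward 20 HU) the
two methods separate: the fixed window clips the lipid tail below −29 HU
while the adaptive boundary follows it, so the mixture model measures at
least as much muscle — the behavior that makes fixed adult thresholds
questionable in children.

A full case-control study runs from the command line without any input
data:

```bash
trunkcomp demo --out demo_run --seed 1        # 20 cases vs 40 controls
```

writing `subjects.csv`, `measurements.csv`, a `tables/` directory
(method agreement, group comparison, sex and OI-type subgroups,
Bland–Altman plot data) and a manifest with the seed and config hash.
`trunkcomp run --config cfg.yaml`, `trunkcomp segment` and
`trunkcomp analyze` expose the same pipeline for real NIfTI/DICOM volumes
and externally produced measurement tables.

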