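"""Trunk-muscle segmentation: fixed HU thresholds and the adaptive
two-Gaussian histogram model.

Two methods measure the same thing — muscle cross-sectional area (cm^2) and
mean density (HU) inside a caller-supplied fascia ROI — but differ in how a
voxel is called muscle:

**Fixed thresholds.**  Muscle is any ROI voxel in the adult anatomical
window, with the fat/muscle cut at -29 HU: HU in [-29, 150], after removing
bone.  Bone is delineated as hole-filled connected components seeded from
voxels >= 150 HU, so fat-like marrow inside a cortical shell is excluded
along with the shell.

**Gaussian-mixture thresholds.**  The HU histogram of the intrafascial
compartment is bimodal — adipose tissue peaks near -100 HU, the
muscle-lipid system near +40 HU.  A sum of two Gaussians
``a_f*exp(-(x-b_f)^2/(2 c_f^2)) + a_m*exp(-(x-b_m)^2/(2 c_m^2))`` is fitted
to the binned spectrum by damped least squares (Levenberg-Marquardt).
Voxels brighter than the muscle peak ``b_m`` seed a 3-D region growing
(26-connected) constrained to the ROI slab; growth admits voxels down to
the intersection of the two fitted curves — the image-specific analogue of
the universal -29 HU cut — with ``b_m - 2 c_m`` as fallback when the curves
do not cross between the peaks.  This adapts the fat/muscle boundary to the
subject's own fat content and scanner calibration, which matters in
children, where the adult window misclassifies lipid-rich muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .ct_io import CTVolume, FasciaROI
from .errors import (
    DegenerateFitError,
    EmptySegmentationError,
    FitFailureError,
    NoSeedError,
)

#: adult anatomical muscle window and fat/muscle cut, HU
FIXED_RANGE = (-30.0, 150.0)
FAT_MUSCLE_CUT = -29.0
CORTICAL_BONE_HU = 150.0
HIST_RANGE = (-200, 200)
HIST_BIN_WIDTH = 1


@dataclass(frozen=True)
class GaussianCurve:
    """One fitted population: height (counts), peak location and width (HU)."""

    height: float
    peak: float
    width: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.height * np.exp(-((x - self.peak) ** 2) / (2.0 * self.width ** 2))


@dataclass
class MixtureFit:
    """Two-Gaussian fit of an ROI HU spectrum and the thresholds it implies.

    ``seed_threshold`` is the muscle peak ``b_m``; ``lower_growth_threshold``
    is the HU where the adipose and muscle curves intersect between the two
    peaks (equal-count boundary), the image-specific fat/muscle cut.
    """

    adipose: GaussianCurve
    muscle: GaussianCurve
    bin_centers: np.ndarray
    counts: np.ndarray
    residual_norm: float
    converged: bool
    seed_threshold: float
    lower_growth_threshold: float

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.adipose.height, self.adipose.peak, self.adipose.width,
                self.muscle.height, self.muscle.peak, self.muscle.width)


@dataclass
class SegmentationResult:
    """Muscle mask plus the two endpoints on one evaluation slice."""

    muscle_mask: np.ndarray  # 2-D boolean, evaluation slice
    method: str  # 'fixed' | 'gmm'
    level_tag: str
    area_cm2: float
    density_hu: float  # NaN when the mask is empty
    bone_area_cm2: float
    fit: Optional[MixtureFit] = None
    flags: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.muscle_mask.any()


def _require_roi(roi: FasciaROI, hu_slice: np.ndarray) -> None:
    if roi.mask.shape != hu_slice.shape:
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} != slice shape {hu_slice.shape}")


def bone_mask(hu_slice: np.ndarray, roi: FasciaROI,
              cortical_threshold: float = CORTICAL_BONE_HU) -> np.ndarray:
    """Bone on one slice: hole-filled components seeded from cortical voxels.

    Every connected component of HU strictly above ``cortical_threshold``
    inside the ROI is kept and its interior holes are filled, so a marrow
    cavity (fat-like HU) surrounded by cortical bone counts as bone, not as
    fat or muscle.  The strict inequality keeps the bone seed disjoint from
    the muscle window, whose inclusive upper bound is the same 150 HU.
    """
    _require_roi(roi, hu_slice)
    cortical = (np.asarray(hu_slice, dtype=float) > cortical_threshold) & roi.mask
    if not cortical.any():
        return np.zeros_like(roi.mask)
    return ndimage.binary_fill_holes(cortical)


def segment_fixed_threshold(
    hu_slice: np.ndarray,
    roi: FasciaROI,
    pixel_spacing: tuple[float, float],
    hu_range: tuple[float, float] = FIXED_RANGE,
    fat_cut: float = FAT_MUSCLE_CUT,
) -> SegmentationResult:
    """Fixed-window segmentation: muscle = ROI voxels with
    ``fat_cut <= HU <= hu_range[1]``, minus bone.

    The window lower bound (-30 HU) delimits anatomical muscle from fat on
    the fat side; the fat/muscle cut (-29 HU) is the first HU value counted
    as muscle tissue, so -30 belongs to fat and -29 to muscle.
    """
    _require_roi(roi, hu_slice)
    if not hu_range[0] < fat_cut <= hu_range[1]:
        raise ValueError(
            f"need range lower < fat_cut <= range upper; got {hu_range}, {fat_cut}")
    hu = np.asarray(hu_slice, dtype=float)
    bone = bone_mask(hu_slice, roi)
    mask = roi.mask & (hu >= fat_cut) & (hu <= hu_range[1]) & ~bone
    pixel_area_cm2 = pixel_spacing[0] * pixel_spacing[1] / 100.0
    flags = [] if mask.any() else ["empty_segmentation"]
    return SegmentationResult(
        muscle_mask=mask, method="fixed", level_tag=roi.level_tag,
        area_cm2=float(mask.sum()) * pixel_area_cm2,
        density_hu=float(hu[mask].mean()) if mask.any() else float("nan"),
        bone_area_cm2=float(bone.sum()) * pixel_area_cm2,
        flags=flags)


def build_hu_histogram(
    values: np.ndarray,
    bin_width: float = HIST_BIN_WIDTH,
    hu_range: tuple[float, float] = HIST_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of HU values on a fixed integer-centered bin grid.

    Bins are centered on multiples of ``bin_width`` covering ``hu_range``
    (closed), so integer HU data land exactly on bin centers.  Voxels
    outside the range are excluded.  Returns ``(bin_centers, counts)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptySegmentationError("no voxels supplied to histogram")
    centers = np.arange(hu_range[0], hu_range[1] + bin_width / 2.0, bin_width)
    edges = np.concatenate([centers - bin_width / 2.0,
                            [centers[-1] + bin_width / 2.0]])
    counts, _ = np.histogram(values, bins=edges)
    if counts.sum() == 0:
        raise EmptySegmentationError(
            f"all voxels outside histogram range {hu_range}")
    return centers, counts.astype(float)


def _two_gaussian_model(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    af, bf, cf, am, bm, cm = p
    return (af * np.exp(-((x - bf) ** 2) / (2.0 * cf ** 2))
            + am * np.exp(-((x - bm) ** 2) / (2.0 * cm ** 2)))


def gaussian_intersection(adipose: GaussianCurve, muscle: GaussianCurve
                          ) -> Optional[float]:
    """HU where the two curves have equal count, between the two peaks.

    Equating the Gaussians and taking logs gives a quadratic in x; the root
    inside the open interval (adipose.peak, muscle.peak) is returned, or
    None when no crossing exists there (e.g. one curve dominates throughout).
    """
    af, bf, cf = adipose.height, adipose.peak, adipose.width
    am, bm, cm = muscle.height, muscle.peak, muscle.width
    if af <= 0 or am <= 0:
        return None
    # log a_f - (x-b_f)^2/(2c_f^2) = log a_m - (x-b_m)^2/(2c_m^2)
    A = 1.0 / (2 * cm ** 2) - 1.0 / (2 * cf ** 2)
    B = bf / cf ** 2 - bm / cm ** 2
    C = (bm ** 2 / (2 * cm ** 2) - bf ** 2 / (2 * cf ** 2)
         + np.log(af) - np.log(am))
    if abs(A) < 1e-12:  # equal widths: linear equation
        if abs(B) < 1e-12:
            return None
        roots = [-C / B]
    else:
        disc = B ** 2 - 4 * A * C
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    inside = [r for r in roots if bf < r < bm]
    if not inside:
        return None
    return float(min(inside, key=lambda r: abs(r - (bf + bm) / 2)))


def _default_init(centers: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Initial parameters: peaks at the histogram modes below -30 HU and
    above 0 HU, widths 10 HU, adipose height from the adipose/muscle
    voxel-count ratio."""
    below = centers < -30
    above = centers > 0
    bf = centers[below][np.argmax(counts[below])]
    bm = centers[above][np.argmax(counts[above])]
    n_adipose = counts[centers < -30].sum()
    n_muscle = counts[centers >= -29].sum()
    am = float(counts[above].max())
    ratio = n_adipose / n_muscle if n_muscle > 0 else 1.0
    af = max(am * ratio, float(np.finfo(float).tiny))
    return np.array([af, bf, 10.0, am, bm, 10.0])


def fit_two_gaussians(
    histogram: tuple[np.ndarray, np.ndarray],
    init: Optional[Sequence[float]] = None,
    max_iterations: int = 2000,
) -> MixtureFit:
    """Fit the two-Gaussian model to an HU histogram by damped least squares.

    The fit runs on (bin center, count) pairs — curve fitting to the
    spectrum, not expectation-maximization on voxels.  Curves are ordered so
    the adipose peak lies below the muscle peak.  Raises
    :class:`DegenerateFitError` when the spectrum does not contain two
    populations (fewer than 3 informative bins on either side of -30 HU),
    and :class:`FitFailureError` (carrying the last iterate) when the
    optimizer does not converge.
    """
    centers, counts = histogram
    centers = np.asarray(centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    order = np.argsort(centers)
    centers, counts = centers[order], counts[order]

    # informative bins: above numerical dust relative to the spectrum peak
    informative = counts > max(1e-3 * counts.max(), 0.0)
    n_below = int((informative & (centers < -30)).sum())
    n_above = int((informative & (centers > -30)).sum())
    if informative.sum() < 6 or n_below < 3 or n_above < 3:
        raise DegenerateFitError(
            "histogram does not show two populations "
            f"({n_below} informative bins below -30 HU, {n_above} above)")

    p0 = np.asarray(init, dtype=float) if init is not None \
        else _default_init(centers, counts)

    def residuals(p):
        return _two_gaussian_model(centers, p) - counts

    res = optimize.least_squares(residuals, p0, method="lm",
                                 max_nfev=max_iterations * len(p0))
    p = res.x.copy()
    p[2], p[5] = abs(p[2]), abs(p[5])  # widths enter squared; fix sign
    curves = sorted([GaussianCurve(p[0], p[1], p[2]),
                     GaussianCurve(p[3], p[4], p[5])], key=lambda g: g.peak)
    adipose, muscle = curves
    residual_norm = float(np.linalg.norm(res.fun))

    def build(converged: bool) -> MixtureFit:
        inter = gaussian_intersection(adipose, muscle)
        lower = inter if inter is not None else muscle.peak - 2.0 * muscle.width
        return MixtureFit(adipose=adipose, muscle=muscle, bin_centers=centers,
                          counts=counts, residual_norm=residual_norm,
                          converged=converged, seed_threshold=muscle.peak,
                          lower_growth_threshold=float(lower))

    if res.status <= 0:
        raise FitFailureError(
            f"damped least squares did not converge: {res.message}",
            last_fit=build(False))
    if not (adipose.peak < muscle.peak) or adipose.width <= 0 or muscle.width <= 0 \
            or adipose.height < 0 or muscle.height < 0:
        raise DegenerateFitError(
            f"fit collapsed to a degenerate configuration: peaks "
            f"({adipose.peak:.1f}, {muscle.peak:.1f}), "
            f"widths ({adipose.width:.1f}, {muscle.width:.1f})")
    return build(True)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def region_grow(
    hu: np.ndarray,
    roi_slab: np.ndarray,
    seeds: np.ndarray,
    lower_threshold: float,
) -> np.ndarray:
    """3-D seeded region growing inside an ROI slab.

    Returns the maximal set of slab voxels reachable from the seeds through
    26-connected paths of voxels with HU >= ``lower_threshold``.  Implemented
    as connected-component labeling of the thresholded slab restricted to
    components containing at least one seed — equivalent to breadth-first
    growth and monotone in the threshold (lower threshold, larger mask).
    """
    hu = np.asarray(hu, dtype=float)
    roi_slab = np.asarray(roi_slab, dtype=bool)
    seeds = np.asarray(seeds, dtype=bool)
    if hu.shape != roi_slab.shape or hu.shape != seeds.shape:
        raise ValueError("hu, roi_slab and seeds must share one 3-D shape")
    if not seeds.any():
        raise NoSeedError("region growing requires at least one seed voxel")
    if not (seeds & ~roi_slab).sum() == 0:
        raise ValueError("seeds must lie inside the ROI slab")
    admissible = roi_slab & (hu >= lower_threshold)
    labels, _ = ndimage.label(admissible, structure=_CONN26)
    seed_labels = np.unique(labels[seeds & admissible])
    seed_labels = seed_labels[seed_labels > 0]
    return np.isin(labels, seed_labels)


def segment_gmm(
    volume: CTVolume,
    roi: FasciaROI,
    slab_halfwidth: int = 5,
    fallback_fixed: bool = True,
) -> SegmentationResult:
    """Gaussian-mixture segmentation on the ROI slice of a volume.

    Pipeline: build the HU histogram of the ROI slab (ROI mask propagated
    to ``slab_halfwidth`` slices either side, bone excluded), fit the
    two-Gaussian model, seed from voxels strictly above the muscle peak,
    grow in 3-D down to the curve-intersection threshold, then measure area
    and density on the ROI slice only.

    A single-population spectrum (e.g. no intermuscular fat) cannot anchor
    the adipose curve; with ``fallback_fixed`` the fixed-threshold result is
    returned flagged ``gmm_degenerate_fallback_fixed``, otherwise
    :class:`DegenerateFitError` propagates.
    """
    idx = roi.slice_index
    if not 0 <= idx < volume.n_slices:
        raise ValueError(f"ROI slice {idx} outside volume with {volume.n_slices} slices")
    _require_roi(roi, volume.voxels[idx])
    lo = max(0, idx - slab_halfwidth)
    hi = min(volume.n_slices - 1, idx + slab_halfwidth)
    hu_slab = np.asarray(volume.voxels[lo:hi + 1], dtype=float)
    roi_slab = np.broadcast_to(roi.mask, hu_slab.shape).copy()

    # bone excluded before histogram, seeding and growth
    bone_slab = np.zeros_like(roi_slab)
    for k in range(hu_slab.shape[0]):
        bone_slab[k] = bone_mask(hu_slab[k], roi)
    domain = roi_slab & ~bone_slab
    pixel_spacing = (volume.spacing[1], volume.spacing[2])
    pixel_area_cm2 = pixel_spacing[0] * pixel_spacing[1] / 100.0
    bone_area = float(bone_slab[idx - lo].sum()) * pixel_area_cm2

    try:
        hist = build_hu_histogram(hu_slab[domain])
        fit = fit_two_gaussians(hist)
    except DegenerateFitError:
        if not fallback_fixed:
            raise
        result = segment_fixed_threshold(volume.voxels[idx], roi, pixel_spacing)
        result.method = "gmm"
        result.flags.append("gmm_degenerate_fallback_fixed")
        return result

    seeds = domain & (hu_slab > fit.seed_threshold)
    if not seeds.any():
        return SegmentationResult(
            muscle_mask=np.zeros_like(roi.mask), method="gmm",
            level_tag=roi.level_tag, area_cm2=0.0, density_hu=float("nan"),
            bone_area_cm2=bone_area, fit=fit, flags=["empty_segmentation"])
    grown = region_grow(hu_slab, domain, seeds, fit.lower_growth_threshold)
    mask = grown[idx - lo]
    flags = [] if mask.any() else ["empty_segmentation"]
    hu_eval = hu_slab[idx - lo]
    return SegmentationResult(
        muscle_mask=mask, method="gmm", level_tag=roi.level_tag,
        area_cm2=float(mask.sum()) * pixel_area_cm2,
        density_hu=float(hu_eval[mask].mean()) if mask.any() else float("nan"),
        bone_area_cm2=bone_area, fit=fit, flags=flags)
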