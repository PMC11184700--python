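"""Synthetic chest-cross-section CT phantoms and synthetic cohorts.

Every downstream stage (ROI handling, both segmentation methods, the
statistics layer) is exercised against phantoms with analytically known
ground truth, because raw patient CT volumes are not available.  A phantom
is a stack of 2.5-D compartments — per-slice ellipses, annuli or boxes
extruded over a slab — each filled with independent normal HU noise:

* muscle          ~ N(45, 5) HU      (lean trunk muscle)
* adipose         ~ N(-100, 15) HU   (intermuscular fat)
* cortical bone   > 150 HU, as an annulus around
* marrow          fat-like HU core   (the hard case for bone subtraction)
* air/background  -1000 HU

Voxel values are rounded to integer HU and clipped to the CT dynamic range
[-1024, 3071], matching how scanners store reconstructions.  The fascia ROI
ground truth is the union of the soft-tissue and bone compartments, i.e.
everything inside the perimuscular deep fascia.

Cohort generation is separate: it draws per-subject measurement values whose
sample mean and SD match requested group targets *exactly* (z-score then
affine rescale), so printed summary statistics of a study population can be
reproduced deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .ct_io import HU_MAX, HU_MIN, CTVolume, FasciaROI
from .errors import GeometryConflictError, InvalidSpecError

COMPARTMENT_LABELS = ("muscle", "adipose", "bone", "marrow", "air")
#: labels making up the intrafascial compartment (inside the deep fascia)
FASCIA_LABELS = ("muscle", "adipose", "bone", "marrow")


# ---------------------------------------------------------------------------
# Geometry primitives (pixel centers at integer (row, col) coordinates)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse extruded over a slice slab (inclusive)."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (row, col) semi-axis lengths, pixels
    slab: tuple[int, int]  # (first_slice, last_slice) inclusive

    def footprint(self, slice_shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0:slice_shape[0], 0:slice_shape[1]]
        ar, ac = self.semi_axes
        if ar <= 0 or ac <= 0:
            raise InvalidSpecError("ellipse semi-axes must be positive")
        return (((rr - self.center[0]) / ar) ** 2
                + ((cc - self.center[1]) / ac) ** 2) <= 1.0

    def bbox(self) -> tuple[float, float, float, float]:
        return (self.center[0] - self.semi_axes[0], self.center[0] + self.semi_axes[0],
                self.center[1] - self.semi_axes[1], self.center[1] + self.semi_axes[1])


@dataclass(frozen=True)
class Annulus:
    """Elliptical ring: outer ellipse minus inner ellipse, same center.

    The excluded interior is exactly the footprint of ``Ellipse(center,
    inner_semi_axes)``, so a ring and a core with matching axes tile without
    gap or overlap — used for cortical bone around marrow.
    """

    center: tuple[float, float]
    outer_semi_axes: tuple[float, float]
    inner_semi_axes: tuple[float, float]
    slab: tuple[int, int]

    def footprint(self, slice_shape: tuple[int, int]) -> np.ndarray:
        outer = Ellipse(self.center, self.outer_semi_axes, self.slab)
        inner = Ellipse(self.center, self.inner_semi_axes, self.slab)
        if not all(o > i for o, i in zip(self.outer_semi_axes, self.inner_semi_axes)):
            raise InvalidSpecError("annulus outer semi-axes must exceed inner")
        return outer.footprint(slice_shape) & ~inner.footprint(slice_shape)

    def bbox(self):
        return Ellipse(self.center, self.outer_semi_axes, self.slab).bbox()


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, inclusive pixel index ranges."""

    rows: tuple[int, int]  # (first, last) inclusive
    cols: tuple[int, int]
    slab: tuple[int, int]

    def footprint(self, slice_shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(slice_shape, dtype=bool)
        mask[self.rows[0]:self.rows[1] + 1, self.cols[0]:self.cols[1] + 1] = True
        return mask

    def bbox(self):
        return (self.rows[0], self.rows[1], self.cols[0], self.cols[1])


Shape = Ellipse | Annulus | Box


@dataclass(frozen=True)
class CompartmentSpec:
    """A tissue compartment: label, HU distribution and geometry."""

    label: str
    mean_hu: float
    sd_hu: float
    shape: Shape

    def __post_init__(self):
        if self.label not in COMPARTMENT_LABELS:
            raise InvalidSpecError(f"label must be one of {COMPARTMENT_LABELS}")
        if self.sd_hu < 0:
            raise InvalidSpecError("sd_hu must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int]  # (slices, rows, cols)
    spacing: tuple[float, float, float]  # mm (slice, row, col)
    compartments: tuple[CompartmentSpec, ...]
    background_hu: float = -1000.0
    noise_seed: int = 0
    evaluation_slice: Optional[int] = None  # default: middle slice
    level_tag: str = "midT4"

    def __post_init__(self):
        if any(int(n) < 1 for n in self.volume_shape):
            raise InvalidSpecError(f"volume_shape must be >= 1 per axis: {self.volume_shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError(f"spacing must be positive: {self.spacing}")
        object.__setattr__(self, "compartments", tuple(self.compartments))

    @property
    def eval_slice(self) -> int:
        if self.evaluation_slice is None:
            return self.volume_shape[0] // 2
        return int(self.evaluation_slice)


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: per-label masks, areas and mean HU."""

    masks: dict[str, np.ndarray]  # label -> 3-D boolean mask
    true_area_cm2: dict[str, float]  # on the evaluation slice
    true_mean_hu: dict[str, float]
    fascia_roi: FasciaROI
    fascia_mask_3d: np.ndarray
    evaluation_slice: int


def _rasterize_compartments(spec: PhantomSpec):
    n_slices, rows, cols = spec.volume_shape
    masks3d = []
    for comp in spec.compartments:
        lo, hi = comp.shape.slab
        if not (0 <= lo <= hi < n_slices):
            raise InvalidSpecError(
                f"compartment {comp.label} slab {comp.shape.slab} outside "
                f"[0, {n_slices})")
        bb = comp.shape.bbox()
        if bb[0] < -0.5 or bb[1] > rows - 0.5 or bb[2] < -0.5 or bb[3] > cols - 0.5:
            raise InvalidSpecError(
                f"compartment {comp.label} geometry exceeds slice bounds")
        foot = comp.shape.footprint((rows, cols))
        m = np.zeros(spec.volume_shape, dtype=bool)
        m[lo:hi + 1] = foot
        masks3d.append(m)

    claimed = np.zeros(spec.volume_shape, dtype=bool)
    for comp, m in zip(spec.compartments, masks3d):
        if (claimed & m).any():
            raise GeometryConflictError(
                f"compartment {comp.label} overlaps a previous compartment "
                "after rasterization")
        claimed |= m
    return masks3d


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom spec into a seeded noisy HU volume plus truth.

    Voxels inside each compartment are drawn i.i.d. from
    N(mean_hu, sd_hu^2), rounded to integer HU and clipped to
    [-1024, 3071].  The same spec (including ``noise_seed``) always yields
    a bit-identical volume.
    """
    masks3d = _rasterize_compartments(spec)
    rng = np.random.default_rng(spec.noise_seed)
    voxels = np.full(spec.volume_shape, float(spec.background_hu))
    for comp, m in zip(spec.compartments, masks3d):
        n = int(m.sum())
        voxels[m] = rng.normal(comp.mean_hu, comp.sd_hu, size=n)
    voxels = np.clip(np.rint(voxels), HU_MIN, HU_MAX).astype(np.int16)

    pixel_area_cm2 = spec.spacing[1] * spec.spacing[2] / 100.0
    eval_idx = spec.eval_slice
    label_masks: dict[str, np.ndarray] = {}
    for comp, m in zip(spec.compartments, masks3d):
        if comp.label in label_masks:
            label_masks[comp.label] = label_masks[comp.label] | m
        else:
            label_masks[comp.label] = m
    true_area = {lab: float(m[eval_idx].sum()) * pixel_area_cm2
                 for lab, m in label_masks.items()}
    true_mean = {}
    for lab in label_masks:
        comps = [c for c, m in zip(spec.compartments, masks3d) if c.label == lab]
        weights = np.array([float(m[eval_idx].sum())
                            for c, m in zip(spec.compartments, masks3d)
                            if c.label == lab])
        means = np.array([c.mean_hu for c in comps])
        true_mean[lab] = float(np.average(means, weights=weights)) \
            if weights.sum() > 0 else float("nan")

    fascia3d = np.zeros(spec.volume_shape, dtype=bool)
    for lab in FASCIA_LABELS:
        if lab in label_masks:
            fascia3d |= label_masks[lab]
    if not fascia3d[eval_idx].any():
        raise InvalidSpecError("no intrafascial compartment on the evaluation slice")
    roi = FasciaROI(slice_index=eval_idx, mask=fascia3d[eval_idx],
                    level_tag=spec.level_tag)

    volume = CTVolume(voxels=voxels, spacing=spec.spacing,
                      source_id=f"phantom(seed={spec.noise_seed})")
    truth = PhantomTruth(masks=label_masks, true_area_cm2=true_area,
                         true_mean_hu=true_mean, fascia_roi=roi,
                         fascia_mask_3d=fascia3d, evaluation_slice=eval_idx)
    return volume, truth


def chest_phantom_spec(
    muscle_mean: float = 45.0,
    muscle_sd: float = 5.0,
    fat_mean: float = -100.0,
    fat_sd: float = 15.0,
    bone_mean: float = 400.0,
    bone_sd: float = 50.0,
    marrow_mean: float = -60.0,
    marrow_sd: float = 20.0,
    volume_shape: tuple[int, int, int] = (12, 128, 128),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_seed: int = 0,
    level_tag: str = "midT4",
    scale: float = 1.0,
) -> PhantomSpec:
    """Standard chest-slice layout: a muscle ring enclosing intermuscular
    fat and a cortical-bone annulus with fat-like marrow.

    ``scale`` shrinks/grows all in-plane geometry (T10 sections are smaller
    than T4).  Defaults give a muscle ring of roughly 43 cm^2 at 1 mm pixels.
    """
    n_slices = volume_shape[0]
    slab = (0, n_slices - 1)
    cr = volume_shape[1] / 2.0
    cc = volume_shape[2] / 2.0
    s = scale
    compartments = (
        CompartmentSpec("muscle", muscle_mean, muscle_sd,
                        Annulus((cr, cc), (44 * s, 50 * s), (26 * s, 32 * s), slab)),
        CompartmentSpec("adipose", fat_mean, fat_sd,
                        Ellipse((cr, cc - 4 * s), (9 * s, 11 * s), slab)),
        CompartmentSpec("bone", bone_mean, bone_sd,
                        Annulus((cr, cc + 20 * s), (8 * s, 8 * s), (5 * s, 5 * s), slab)),
        CompartmentSpec("marrow", marrow_mean, marrow_sd,
                        Ellipse((cr, cc + 20 * s), (5 * s, 5 * s), slab)),
    )
    return PhantomSpec(volume_shape=volume_shape, spacing=spacing,
                       compartments=compartments, noise_seed=noise_seed,
                       level_tag=level_tag)


# ---------------------------------------------------------------------------
# Synthetic cohorts with exact group moments


@dataclass(frozen=True)
class GroupTargets:
    """Per-group sample size and (mean, sd) targets per variable."""

    n: int
    variables: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        if self.n < 2:
            raise InvalidSpecError("group size must be >= 2")
        for var, (mean, sd) in self.variables.items():
            if sd < 0:
                raise InvalidSpecError(f"sd for {var} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    groups: Mapping[str, GroupTargets]
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise InvalidSpecError("at least one group required")


def _exact_moment_sample(rng: np.random.Generator, mean: float, sd: float,
                         n: int) -> np.ndarray:
    """n draws whose sample mean and sample SD (n-1 denominator) equal the
    targets to machine precision."""
    if sd == 0:
        return np.full(n, float(mean))
    x = rng.standard_normal(n)
    while np.std(x, ddof=1) == 0:  # pragma: no cover - probability zero
        x = rng.standard_normal(n)
    z = (x - x.mean()) / np.std(x, ddof=1)
    return mean + sd * z


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a subject table whose per-group sample moments exactly match
    the requested targets.

    Subjects are labeled ``<group>_<i>``.  Variables are generated
    independently; only the marginal group moments are controlled, not
    between-variable correlations.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group in spec.groups:  # insertion order: deterministic
        targets = spec.groups[group]
        data = {"subject_id": [f"{group}_{i:03d}" for i in range(targets.n)],
                "group": group}
        for var in targets.variables:
            mean, sd = targets.variables[var]
            data[var] = _exact_moment_sample(rng, mean, sd, targets.n)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
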