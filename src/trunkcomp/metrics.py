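"""Muscle endpoints: cross-sectional area (cm^2) and mean density (HU),
plus assembly of per-subject measurement tables.

Area is reported raw (no height/weight normalization); density is the
arithmetic mean HU over the muscle mask, a proxy for muscle quality that
falls with intramuscular fat content.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .ct_io import LEVELS, SubjectRecord
from .errors import (
    DuplicateMeasurementError,
    EmptySegmentationError,
    ReferentialIntegrityError,
)
from .segmentation import SegmentationResult

METHODS = ("fixed", "gmm")

MEASUREMENT_COLUMNS = ["subject_id", "level", "method", "area_cm2",
                       "density_hu", "bone_area_cm2", "flags"]


def cross_sectional_area(mask: np.ndarray, pixel_spacing: tuple[float, float]) -> float:
    """Mask area in cm^2: pixel count x (row spacing x col spacing) / 100."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * pixel_spacing[0] * pixel_spacing[1] / 100.0


def mean_density(hu_slice: np.ndarray, mask: np.ndarray) -> float:
    """Mean HU over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(hu_slice):
        raise ValueError("mask and slice shapes differ")
    if not mask.any():
        raise EmptySegmentationError("density is undefined on an empty mask")
    return float(np.asarray(hu_slice, dtype=float)[mask].mean())


def assemble_measurements(
    results: Sequence[tuple[str, SegmentationResult]],
    subjects: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Collect (subject_id, result) pairs into one tidy measurement table.

    One row per (subject, level, method).  Combinations present in the
    subject roster but missing from the results are emitted with NaN values
    and a ``missing`` flag, so gaps are visible rather than silently absent.
    Unknown subjects and duplicate keys are errors.
    """
    known = {s.subject_id for s in subjects}
    rows: dict[tuple[str, str, str], dict] = {}
    for subject_id, res in results:
        if subject_id not in known:
            raise ReferentialIntegrityError(
                f"result for unknown subject {subject_id!r}")
        key = (subject_id, res.level_tag, res.method)
        if key in rows:
            raise DuplicateMeasurementError(
                f"duplicate measurement for {key}")
        rows[key] = {
            "subject_id": subject_id, "level": res.level_tag,
            "method": res.method, "area_cm2": res.area_cm2,
            "density_hu": res.density_hu, "bone_area_cm2": res.bone_area_cm2,
            "flags": "|".join(res.flags)}

    seen_levels = sorted({k[1] for k in rows}, key=LEVELS.index) or list(LEVELS)
    seen_methods = sorted({k[2] for k in rows}, key=METHODS.index) or list(METHODS)
    out = []
    for s in subjects:
        for level in seen_levels:
            for method in seen_methods:
                key = (s.subject_id, level, method)
                if key in rows:
                    out.append(rows[key])
                else:
                    out.append({"subject_id": s.subject_id, "level": level,
                                "method": method, "area_cm2": np.nan,
                                "density_hu": np.nan, "bone_area_cm2": np.nan,
                                "flags": "missing"})
    return pd.DataFrame(out, columns=MEASUREMENT_COLUMNS)
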