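"""CT volume and ROI input/output.

Volumes are held slice-major as ``(slice, row, col)`` arrays of Hounsfield
Units with per-axis spacing in mm.  Chest CT is routinely anisotropic (1 mm
reconstruction interval but in-plane spacing set by the field of view), so
spacing is always carried per axis.  Fascia ROIs — the compartment enclosed
by the perimuscular deep fascia, i.e. muscle plus intermuscular fat,
excluding subcutaneous fat — arrive either as boolean masks or as polygons
drawn on a single axial slice; vertebral-level selection (mid-T4, mid-T10)
is a caller-supplied slice index, mirroring manual level identification.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    BoundsError,
    DegeneratePolygonError,
    FormatIntegrityError,
)

HU_MIN = -1024
HU_MAX = 3071

LEVELS = ("midT4", "midT10")
GROUPS = ("OI", "control")
SEXES = ("male", "female")
OI_TYPES = ("I", "III", "IV", "none")
EXCLUSION_REASONS = ("poor_image_quality", "lost_images")

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"


@dataclass
class CTVolume:
    """A CT volume in Hounsfield Units.

    Parameters
    ----------
    voxels
        ``(n_slices, n_rows, n_cols)`` array of HU values.
    spacing
        mm per axis in ``(slice, row, col)`` order; all components > 0.
    origin
        Physical position of voxel (0, 0, 0) in mm (z, y, x).
    source_id
        Free-form provenance tag (file path, phantom name, series UID).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatIntegrityError(
                f"volume must be 3-D (slice, row, col); got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatIntegrityError(f"spacing must be 3 positive values; got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[1] * self.spacing[2]


@dataclass
class FasciaROI:
    """Per-slice mask of the intrafascial compartment."""

    slice_index: int
    mask: np.ndarray
    level_tag: str = "midT4"
    polygon: Optional[np.ndarray] = None  # (n, 2) vertices as (x, y) pixel coords

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatIntegrityError("ROI mask must be 2-D")
        if not self.mask.any():
            raise FormatIntegrityError("ROI mask is empty")
        if self.level_tag not in LEVELS:
            raise FormatIntegrityError(f"level_tag must be one of {LEVELS}")


@dataclass
class SubjectRecord:
    """One study participant with demographics and exclusion flags."""

    subject_id: str
    group: str
    sex: str
    age: float
    weight: float
    height: float
    bmi: float
    oi_type: str = "none"
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.oi_type not in OI_TYPES:
            raise ValueError(f"oi_type must be one of {OI_TYPES}")
        if (self.oi_type == "none") != (self.group == "control"):
            raise ValueError("oi_type is 'none' if and only if group is 'control'")
        self.exclusion_flags = frozenset(self.exclusion_flags)
        unknown = self.exclusion_flags - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")


@dataclass
class SliceHandle:
    """A designated evaluation slice with its level tag."""

    index: int
    level_tag: str
    hu: np.ndarray
    pixel_spacing: tuple[float, float]  # (row, col) mm


# ---------------------------------------------------------------------------
# Volume I/O


def save_volume_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; HU stored as int16, spacing in the header."""
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.ascontiguousarray(volume.voxels.T)  # nibabel wants (x, y, z)
    img = nib.Nifti1Image(data.astype(np.int16), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def save_mask_nifti(mask: np.ndarray, spacing: tuple[float, float, float],
                    path: str | os.PathLike) -> None:
    """Write a boolean/label mask as a NIfTI label map (uint8)."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    sz, sy, sx = (float(s) for s in spacing)
    img = nib.Nifti1Image(np.ascontiguousarray(mask.T).astype(np.uint8),
                          np.diag([sx, sy, sz, 1.0]))
    nib.save(img, str(path))


def _load_nifti(path: str | os.PathLike) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatIntegrityError(f"expected 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatIntegrityError(f"non-positive voxel spacing in header: {zooms}")
    voxels = np.ascontiguousarray(data.T)  # back to (slice, row, col)
    return CTVolume(voxels=voxels, spacing=(zooms[2], zooms[1], zooms[0]),
                    source_id=str(path))


def save_volume_dicom(volume: CTVolume, directory: str | os.PathLike,
                      series_uid: Optional[str] = None) -> list[Path]:
    """Write a volume as a single-frame CT DICOM series.

    Stored values are unsigned 16-bit with RescaleSlope 1 and
    RescaleIntercept -1024, the usual CT convention, so HU = stored - 1024.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    intercept = -1024
    stored = np.clip(np.rint(volume.voxels) - intercept, 0, 4095).astype(np.uint16)
    sz, sy, sx = volume.spacing
    paths = []
    for i in range(volume.n_slices):
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.origin[0] + i * sz)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = volume.slice_shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[i].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def _load_dicom_series(directory: str | os.PathLike) -> CTVolume:
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatIntegrityError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1 or None in uids:
        raise FormatIntegrityError(f"mixed or missing SeriesInstanceUID: {uids}")
    for ds in datasets:
        if not hasattr(ds, "PixelSpacing"):
            raise FormatIntegrityError("DICOM slice lacks PixelSpacing")

    # order by spatial position, not file name
    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append(hu)
    voxels = np.rint(np.stack(slices)).astype(np.int16)

    sy, sx = (float(v) for v in datasets[0].PixelSpacing)
    if len(datasets) > 1:
        zs = np.array([z_of(ds) for ds in datasets])
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise FormatIntegrityError("duplicate or non-increasing slice positions")
        sz = float(np.median(dz))
    else:
        sz = float(getattr(datasets[0], "SliceThickness", 1.0))
    origin_z = z_of(datasets[0])
    return CTVolume(voxels=voxels, spacing=(sz, sy, sx),
                    origin=(origin_z, 0.0, 0.0), source_id=str(directory))


def load_volume(path: str | os.PathLike, format: str) -> CTVolume:
    """Load a CT volume in HU from NIfTI or a single-frame DICOM series.

    For DICOM, RescaleSlope/RescaleIntercept are applied and slices are
    ordered by spatial position regardless of file naming.
    """
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}; use 'nifti' or 'dicom_series'")


# ---------------------------------------------------------------------------
# ROI handling


def points_in_polygon(points_xy: np.ndarray, vertices_xy: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    The rule must be pinned for reproducible areas: a point is inside when a
    ray to x = +inf crosses the closed polygon boundary an odd number of
    times, which handles self-intersecting contours deterministically.
    """
    pts = np.asarray(points_xy, dtype=float)
    verts = np.asarray(vertices_xy, dtype=float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < x_at)
    return inside


def rasterize_roi(polygon: Sequence[Sequence[float]], slice_shape: tuple[int, int],
                  slice_index: int = 0, level_tag: str = "midT4") -> FasciaROI:
    """Rasterize a closed polygon to a pixel mask.

    A pixel (r, c) covers [r, r+1) x [c, c+1) so its center is
    (x, y) = (c + 0.5, r + 0.5); the pixel belongs to the mask when its
    center is inside the polygon under the even-odd rule.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 (x, y) vertices; got shape {verts.shape}")
    rows, cols = slice_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    centers = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    mask = points_in_polygon(centers, verts).reshape(rows, cols)
    return FasciaROI(slice_index=slice_index, mask=mask,
                     level_tag=level_tag, polygon=verts)


def roi_from_json(path: str | os.PathLike, slice_shape: tuple[int, int]) -> FasciaROI:
    """Load an ROI polygon from JSON {slice_index, level, vertices:[[x,y],...]}."""
    with open(path) as fh:
        obj = json.load(fh)
    return rasterize_roi(obj["vertices"], slice_shape,
                         slice_index=int(obj["slice_index"]),
                         level_tag=obj.get("level", "midT4"))


def roi_to_json(roi: FasciaROI, path: str | os.PathLike) -> None:
    if roi.polygon is None:
        raise ValueError("ROI has no polygon representation")
    with open(path, "w") as fh:
        json.dump({"slice_index": roi.slice_index, "level": roi.level_tag,
                   "vertices": np.asarray(roi.polygon).tolist()}, fh)


def select_mid_slice(volume: CTVolume, level: str, slice_index: int) -> SliceHandle:
    """Return the designated mid-vertebral-body evaluation slice.

    The index is caller-supplied: levels are identified manually on the
    scout/sagittal view, and automated vertebra labeling is out of scope.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if not 0 <= slice_index < volume.n_slices:
        raise BoundsError(
            f"slice index {slice_index} outside [0, {volume.n_slices})")
    return SliceHandle(index=slice_index, level_tag=level,
                       hu=volume.voxels[slice_index],
                       pixel_spacing=(volume.spacing[1], volume.spacing[2]))


# ---------------------------------------------------------------------------
# Subject tables

_SUBJECT_COLUMNS = ["subject_id", "group", "sex", "age", "weight", "height",
                    "bmi", "oi_type", "exclusion_flags"]


def subjects_to_csv(subjects: Sequence[SubjectRecord], path: str | os.PathLike) -> None:
    rows = [{**{k: getattr(s, k) for k in _SUBJECT_COLUMNS[:-1]},
             "exclusion_flags": "|".join(sorted(s.exclusion_flags))}
            for s in subjects]
    pd.DataFrame(rows, columns=_SUBJECT_COLUMNS).to_csv(path, index=False)


def subjects_from_csv(path: str | os.PathLike) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)
    subjects = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in str(row["exclusion_flags"]).split("|") if f)
        subjects.append(SubjectRecord(
            subject_id=row["subject_id"], group=row["group"], sex=row["sex"],
            age=float(row["age"]), weight=float(row["weight"]),
            height=float(row["height"]), bmi=float(row["bmi"]),
            oi_type=row["oi_type"], exclusion_flags=flags))
    return subjects
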