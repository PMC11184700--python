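"""End-to-end orchestration: phantoms or real volumes -> dual segmentation
at two vertebral levels -> measurement table -> statistics tables.

One global seed is fanned out to per-stage substreams
(:class:`numpy.random.SeedSequence`), so a run is fully determined by its
config; the manifest records the seed and a config hash.  Stage failures
are local and non-silent: a bad series is skipped with a flagged manifest
entry instead of corrupting the cohort table, the behavior opportunistic
batch analysis needs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .ct_io import (
    CTVolume,
    FasciaROI,
    SubjectRecord,
    load_volume,
    roi_from_json,
    save_mask_nifti,
    subjects_from_csv,
    subjects_to_csv,
)
from .errors import ConfigError, TrunkCompError
from .metrics import assemble_measurements
from .phantom import (
    CohortSpec,
    GroupTargets,
    chest_phantom_spec,
    generate_cohort,
    generate_phantom,
)
from .segmentation import segment_fixed_threshold, segment_gmm
from .stats import apply_exclusions, build_tables

VALID_METHODS = ("fixed", "gmm")
VALID_LEVELS = ("midT4", "midT10")


@dataclass
class RunConfig:
    """Configuration of one study run."""

    mode: str = "phantom"  # 'phantom' | 'volumes'
    methods: tuple[str, ...] = ("fixed", "gmm")
    levels: tuple[str, ...] = ("midT4", "midT10")
    n_oi: int = 20
    n_control: int = 40
    slab_halfwidth: int = 5
    variant: str = "auto"  # t-test variance handling: auto | pooled | welch
    seed: int = 0
    out_dir: str = "trunkcomp_run"
    save_masks: bool = False
    subjects_csv: Optional[str] = None  # volumes mode
    volumes: tuple[dict, ...] = ()  # volumes mode: {subject_id, path, format, roi}

    def validate(self) -> None:
        if self.mode not in ("phantom", "volumes"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.methods or any(m not in VALID_METHODS for m in self.methods):
            raise ConfigError(f"methods must be a non-empty subset of {VALID_METHODS}")
        if not self.levels or any(l not in VALID_LEVELS for l in self.levels):
            raise ConfigError(f"levels must be a non-empty subset of {VALID_LEVELS}")
        if self.variant not in ("auto", "pooled", "welch"):
            raise ConfigError(f"unknown t-test variant {self.variant!r}")
        if self.mode == "phantom" and (self.n_oi < 2 or self.n_control < 2):
            raise ConfigError("phantom mode needs n >= 2 per group")
        if self.mode == "volumes" and not self.volumes:
            raise ConfigError("volumes mode needs a volume list")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_yaml(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("methods", "levels", "volumes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Demo cohort: phantoms emulating a 20-case / 40-control chest-CT study


def _demo_subjects(rng: np.random.Generator, n_oi: int, n_control: int
                   ) -> list[SubjectRecord]:
    """Subject roster with exactly moment-matched demographics and the
    reference sex / OI-type composition scaled to the requested group sizes."""
    targets = {
        group: GroupTargets(n=n, variables={
            var: reference.DEMOGRAPHICS[var][group]
            for var in reference.DEMOGRAPHICS})
        for group, n in (("OI", n_oi), ("control", n_control))
    }
    table = generate_cohort(CohortSpec(groups=targets,
                                       seed=int(rng.integers(2 ** 31))))
    subjects = []
    for group, n in (("OI", n_oi), ("control", n_control)):
        sub = table[table["group"] == group].reset_index(drop=True)
        n_male = round(n * reference.SEX_COUNTS[group]["male"]
                       / sum(reference.SEX_COUNTS[group].values()))
        if group == "OI":
            frac = {t: c / sum(reference.OI_TYPE_COUNTS.values())
                    for t, c in reference.OI_TYPE_COUNTS.items()}
            n_iii = max(1, round(n * frac["III"]))
            n_iv = max(1, round(n * frac["IV"]))
            types = ["I"] * (n - n_iii - n_iv) + ["III"] * n_iii + ["IV"] * n_iv
        else:
            types = ["none"] * n
        for i, row in sub.iterrows():
            subjects.append(SubjectRecord(
                subject_id=row["subject_id"], group=group,
                sex="male" if i < n_male else "female",
                age=row["age"], weight=row["weight"], height=row["height"],
                bmi=row["bmi"], oi_type=types[i]))
    return subjects


#: per-level in-plane scale of the phantom geometry (T10 sections are smaller)
_LEVEL_SCALE = {"midT4": 1.0, "midT10": 0.72}
#: group effect on phantom muscle HU and size: cases are less dense, smaller
_GROUP_DENSITY = {"OI": (40.0, 5.0), "control": (48.0, 4.5)}
_GROUP_SCALE_FACTOR = {"OI": 0.92, "control": 1.0}


def _demo_phantom(subject: SubjectRecord, level: str,
                  rng: np.random.Generator):
    mean, sd = _GROUP_DENSITY[subject.group]
    muscle_mean = float(rng.normal(mean, sd))
    scale = _LEVEL_SCALE[level] * _GROUP_SCALE_FACTOR[subject.group] \
        * float(rng.normal(1.0, 0.04))
    spec = chest_phantom_spec(
        muscle_mean=muscle_mean, muscle_sd=8.0,
        noise_seed=int(rng.integers(2 ** 31)), level_tag=level,
        scale=float(np.clip(scale, 0.4, 1.2)))
    return generate_phantom(spec)


def run_study(config: RunConfig) -> dict:
    """Execute a full study run; returns the output manifest.

    Outputs under ``config.out_dir``: ``subjects.csv``,
    ``measurements.csv``, ``tables/*.csv``, optional NIfTI masks, and
    ``manifest.json``.  Identical config (including seed) reproduces
    byte-identical CSVs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_subjects, rng_phantoms = (np.random.default_rng(s) for s in ss.spawn(2))
    failures: list[dict] = []

    if config.mode == "phantom":
        subjects = _demo_subjects(rng_subjects, config.n_oi, config.n_control)
        results = []
        for subject in subjects:
            for level in config.levels:
                volume, truth = _demo_phantom(subject, level, rng_phantoms)
                roi = truth.fascia_roi
                results.extend(_segment_one(
                    subject.subject_id, volume, roi, config, out, failures))
    else:
        subjects = subjects_from_csv(config.subjects_csv) \
            if config.subjects_csv else []
        results = []
        for entry in config.volumes:
            sid = entry["subject_id"]
            try:
                volume = load_volume(entry["path"], entry.get("format", "nifti"))
                roi = roi_from_json(entry["roi"], volume.slice_shape)
            except TrunkCompError as exc:
                failures.append({"subject_id": sid, "stage": "load",
                                 "error": type(exc).__name__, "detail": str(exc)})
                continue
            if not subjects or sid not in {s.subject_id for s in subjects}:
                raise ConfigError(f"volume entry references unknown subject {sid!r}")
            results.extend(_segment_one(sid, volume, roi, config, out, failures))

    enrolled, filter_report = apply_exclusions(subjects)
    enrolled_ids = {s.subject_id for s in enrolled}
    results = [(sid, r) for sid, r in results if sid in enrolled_ids]
    measurements = assemble_measurements(results, enrolled)

    subjects_to_csv(subjects, out / "subjects.csv")
    measurements.to_csv(out / "measurements.csv", index=False,
                        float_format="%.6f")
    tables = build_tables(measurements, enrolled, variant=config.variant)
    for name, df in tables.items():
        df.to_csv(out / "tables" / f"{name}.csv", index=False,
                  float_format="%.6f")

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_screened": filter_report.n_screened,
        "n_enrolled": filter_report.n_enrolled,
        "n_excluded_by_reason": filter_report.n_excluded_by_reason,
        "n_measurement_rows": int(len(measurements)),
        "failures": failures,
        "tables": sorted(tables),
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _segment_one(subject_id: str, volume: CTVolume, roi: FasciaROI,
                 config: RunConfig, out: Path, failures: list[dict]):
    results = []
    for method in config.methods:
        try:
            if method == "fixed":
                res = segment_fixed_threshold(
                    volume.voxels[roi.slice_index], roi,
                    (volume.spacing[1], volume.spacing[2]))
            else:
                res = segment_gmm(volume, roi,
                                  slab_halfwidth=config.slab_halfwidth)
        except TrunkCompError as exc:
            failures.append({"subject_id": subject_id, "stage": f"segment[{method}]",
                             "error": type(exc).__name__, "detail": str(exc)})
            continue
        if config.save_masks:
            mask_dir = out / "masks"
            mask_dir.mkdir(exist_ok=True)
            save_mask_nifti(res.muscle_mask, volume.spacing,
                            mask_dir / f"{subject_id}_{roi.level_tag}_{method}.nii.gz")
        results.append((subject_id, res))
    return results


def _versions() -> dict[str, str]:
    import nibabel
    import pydicom
    import scipy

    from . import __version__

    return {"trunkcomp": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "nibabel": nibabel.__version__, "pydicom": pydicom.__version__}
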