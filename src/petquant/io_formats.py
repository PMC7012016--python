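"""Readers/writers for on-disk artifacts and validated run configuration.

File contracts:

* images and masks — NIfTI-1 (``.nii`` / ``.nii.gz``); masks stored uint8 0/1
* frame timing — 2-column TSV (``frame_start_s``, ``frame_end_s``) with
  header, or the Turku SIF dialect (first line header, then
  ``start end counts1 counts2`` rows; only columns 1-2 are consumed)
* TACs — TSV with a ``# unit:`` comment line then
  ``t_mid_min  frame_dur_min  value`` columns
* config — YAML (primary) or JSON, schema-validated, unknown keys rejected
* run report — JSON
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    DynamicImage,
    FrameSchedule,
    LabelVolume,
    TimeActivityCurve,
    ValidationError,
    VoxelMask,
)

SUPPORTED_MODELS = (
    "srtm", "suvr", "logan_ref", "patlak_ref",
    "logan_plasma", "patlak_plasma", "fur", "tcm2",
)
SUPPORTED_REFERENCE_REGIONS = ("cerebellar_cortex", "occipital_cortex")
SUPPORTED_CORRECTIONS = ("erode", "lateral_cut", "none")
GRAPHICAL_MODELS = ("logan_ref", "patlak_ref", "logan_plasma", "patlak_plasma")

# FreeSurfer color-table defaults (overridable in config)
CEREBELLAR_CORTEX_LABELS = [8, 47]
# aparc occipital parcels: cuneus, lateral occipital, lingual, pericalcarine
OCCIPITAL_CORTEX_LABELS = [1005, 2005, 1011, 2011, 1013, 2013, 1021, 2021]
LATERAL_VENTRICLE_LABELS = [4, 43]

SUPPORTED_TRACERS = ("carfentanil", "raclopride", "madam", "pib")


# ---------------------------------------------------------------------------
# Tracer configuration
# ---------------------------------------------------------------------------


@dataclass
class TracerConfig:
    """Validated per-tracer processing configuration."""

    tracer: str
    reference_region: str
    model: str
    model_params: dict = field(default_factory=dict)
    tail_exclusion: bool = True
    anatomical_correction: str = "erode"
    erosion_depth: int = 1
    reference_labels: list = field(default_factory=list)
    ventricle_labels: list = field(default_factory=lambda: list(LATERAL_VENTRICLE_LABELS))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.model not in SUPPORTED_MODELS:
            raise ValidationError(
                f"model: {self.model!r} not in supported set {SUPPORTED_MODELS}")
        if self.reference_region not in SUPPORTED_REFERENCE_REGIONS:
            raise ValidationError(
                f"reference_region: {self.reference_region!r} not in "
                f"{SUPPORTED_REFERENCE_REGIONS}")
        if self.anatomical_correction not in SUPPORTED_CORRECTIONS:
            raise ValidationError(
                f"anatomical_correction: {self.anatomical_correction!r} not in "
                f"{SUPPORTED_CORRECTIONS}")
        if self.model == "suvr" and "suvr_window" not in self.model_params:
            raise ValidationError("model_params.suvr_window: required for model 'suvr'")
        if self.model in GRAPHICAL_MODELS and "t_star" not in self.model_params:
            raise ValidationError(f"model_params.t_star: required for model {self.model!r}")
        if self.erosion_depth < 1:
            raise ValidationError("erosion_depth must be >= 1")
        if not self.reference_labels:
            self.reference_labels = list(
                CEREBELLAR_CORTEX_LABELS
                if self.reference_region == "cerebellar_cortex"
                else OCCIPITAL_CORTEX_LABELS
            )
        self.reference_labels = [int(x) for x in self.reference_labels]
        self.ventricle_labels = [int(x) for x in self.ventricle_labels]

    def to_dict(self) -> dict:
        return asdict(self)


def default_tracer_config(tracer: str) -> TracerConfig:
    """Built-in defaults for the four supported tracers.

    carfentanil: SRTM, occipital cortex reference, lateral-ventricle cut.
    raclopride / madam: SRTM, cerebellar cortex reference, erosion.
    pib: SUV-ratio over [60, 90] min, cerebellar cortex reference, erosion.
    Tail exclusion is on for all tracers.
    """
    tracer = tracer.lower()
    if tracer not in SUPPORTED_TRACERS:
        raise ValidationError(
            f"unknown tracer {tracer!r}; supported: {', '.join(SUPPORTED_TRACERS)}")
    if tracer == "carfentanil":
        return TracerConfig(tracer=tracer, reference_region="occipital_cortex",
                            model="srtm", anatomical_correction="lateral_cut")
    if tracer == "pib":
        return TracerConfig(tracer=tracer, reference_region="cerebellar_cortex",
                            model="suvr", model_params={"suvr_window": [60.0, 90.0]},
                            anatomical_correction="erode")
    # raclopride, madam
    return TracerConfig(tracer=tracer, reference_region="cerebellar_cortex",
                        model="srtm", anatomical_correction="erode")


_CONFIG_KEYS = {
    "tracer", "reference_region", "model", "model_params", "tail_exclusion",
    "anatomical_correction", "erosion_depth", "reference_labels",
    "ventricle_labels", "seed",
}


def load_config(path) -> TracerConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    missing = {"tracer", "reference_region", "model"} - set(data)
    if missing:
        raise ValidationError(f"missing required config keys: {sorted(missing)}")
    return TracerConfig(**data)


def save_config(cfg: TracerConfig, path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Frame timing
# ---------------------------------------------------------------------------


def load_timing(path) -> FrameSchedule:
    """Read frame timing from TSV (``frame_start_s``/``frame_end_s``) or SIF."""
    path = Path(path)
    if path.suffix.lower() == ".sif":
        return _load_sif(path)
    df = pd.read_csv(path, sep="\t")
    required = {"frame_start_s", "frame_end_s"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"timing TSV must have columns {sorted(required)}, got {list(df.columns)}")
    return FrameSchedule(df["frame_start_s"].to_numpy(float),
                         df["frame_end_s"].to_numpy(float))


def _load_sif(path: Path) -> FrameSchedule:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValidationError("SIF file must have a header line and at least one frame")
    starts, ends = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) < 2:
            raise ValidationError(f"malformed SIF frame line: {ln!r}")
        starts.append(float(parts[0]))
        ends.append(float(parts[1]))
    return FrameSchedule(np.array(starts), np.array(ends))


def save_timing(schedule: FrameSchedule, path) -> None:
    df = pd.DataFrame({"frame_start_s": schedule.start_s, "frame_end_s": schedule.end_s})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NIfTI images, masks, labels
# ---------------------------------------------------------------------------


def load_dynamic_image(path, timing_path) -> DynamicImage:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D NIfTI, got ndim={data.ndim}")
    schedule = load_timing(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise ValidationError(
            f"image has {data.shape[3]} frames but timing file has "
            f"{schedule.n_frames} rows")
    return DynamicImage(voxels=data, affine=np.asarray(img.affine), schedule=schedule)


def save_dynamic_image(image: DynamicImage, path, timing_path=None) -> None:
    nii = nib.Nifti1Image(image.voxels.astype(np.float32), image.affine)
    nib.save(nii, str(path))
    if timing_path is not None:
        save_timing(image.schedule, timing_path)


def load_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(voxels=np.asarray(img.get_fdata()) > 0.5,
                     affine=np.asarray(img.affine))


def save_mask(mask: VoxelMask, path) -> None:
    nii = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(nii, str(path))


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int32)
    return LabelVolume(voxels=data, affine=np.asarray(img.affine))


def save_labels(labels: LabelVolume, path) -> None:
    nii = nib.Nifti1Image(labels.voxels.astype(np.int16), labels.affine)
    nib.save(nii, str(path))


def save_parametric_map(data3d: np.ndarray, affine: np.ndarray, out_dir, stem: str,
                        param: str) -> Path:
    """Write one parametric map as ``<stem>_<param>.nii.gz`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_{param.lower()}.nii.gz"
    nib.save(nib.Nifti1Image(np.asarray(data3d, dtype=np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# TAC TSV
# ---------------------------------------------------------------------------


def save_tac(tac: TimeActivityCurve, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit: {tac.unit}\n")
        fh.write("t_mid_min\tframe_dur_min\tvalue\n")
        for t, d, v in zip(tac.t_mid, tac.frame_dur, tac.value):
            fh.write(f"{t:.10g}\t{d:.10g}\t{v:.10g}\n")


def load_tac(path) -> TimeActivityCurve:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# unit:"):
        raise ValidationError("TAC TSV must start with a '# unit:' comment line")
    unit = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"t_mid_min", "frame_dur_min", "value"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"TAC TSV must have columns {sorted(required)}, got {list(df.columns)}")
    return TimeActivityCurve(t_mid=df["t_mid_min"].to_numpy(float),
                             value=df["value"].to_numpy(float),
                             unit=unit,
                             frame_dur=df["frame_dur_min"].to_numpy(float))


def load_plasma_tsv(path):
    """Plasma input TSV with columns ``t_min`` and ``activity_kbq_ml``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"t_min", "activity_kbq_ml"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"plasma TSV must have columns {sorted(required)}, got {list(df.columns)}")
    from .kinetics import PlasmaInput

    return PlasmaInput(t=df["t_min"].to_numpy(float),
                       cp=df["activity_kbq_ml"].to_numpy(float))


def save_plasma_tsv(plasma, path) -> None:
    df = pd.DataFrame({"t_min": plasma.t, "activity_kbq_ml": plasma.cp})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Per-stage provenance record, serialized to JSON.

    Deliberately contains no wall-clock timestamps so that identical inputs
    and seed yield byte-identical reports; timing is emitted to logging only.
    """

    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = ""
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, inputs: dict | None = None,
                  params: dict | None = None, outputs: dict | None = None) -> None:
        self.stages.append({
            "stage": name,
            "inputs": _jsonable(inputs or {}),
            "params": _jsonable(params or {}),
            "outputs": _jsonable(outputs or {}),
        })

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": _jsonable(self.config),
            "stages": self.stages,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
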