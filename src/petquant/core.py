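"""Core domain types and time-activity-curve arithmetic.

Conventions used throughout the package:

* Internal time unit is **minutes** (kinetic rate constants are 1/min).
  On-disk frame timing is in seconds and converted at the I/O boundary.
* Images are assumed decay-corrected to injection time; no decay handling
  occurs anywhere in the package.
* World coordinates follow the RAS convention of the NIfTI affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SEC_PER_MIN = 60.0

#: unit tags for radioactivity values
UNIT_KBQ_ML = "kBq/ml"
UNIT_SUV = "SUV g/ml"

#: tolerance on affine elements when two grids must match
AFFINE_TOL = 1e-4


class PetQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(PetQuantError):
    """Invalid inputs, broken invariants, schema violations (exit code 2)."""


class NumericalError(PetQuantError):
    """Optimizer / numerical failures (exit code 3)."""


class StageError(PetQuantError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")


# ---------------------------------------------------------------------------
# Frame timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing in seconds from injection.

    Frames must be sorted, non-overlapping (gaps allowed) and each frame
    must have positive duration.
    """

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or end.ndim != 1 or start.size != end.size:
            raise ValidationError("frame_start and frame_end must be 1-D and equal length")
        if start.size == 0:
            raise ValidationError("schedule must contain at least one frame")
        if not np.all(end > start):
            raise ValidationError("every frame must satisfy end > start")
        if not np.all(np.diff(start) > 0):
            raise ValidationError("frames must be sorted by start time")
        if start.size > 1 and not np.all(end[:-1] <= start[1:] + 1e-9):
            raise ValidationError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.start_s + self.end_s) / 2.0 / SEC_PER_MIN

    @property
    def dur_min(self) -> np.ndarray:
        """Frame durations in minutes."""
        return (self.end_s - self.start_s) / SEC_PER_MIN

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / SEC_PER_MIN

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / SEC_PER_MIN


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times ``(start+end)/2`` converted to minutes."""
    return schedule.mid_min


# ---------------------------------------------------------------------------
# Images and masks
# ---------------------------------------------------------------------------


def _check_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValidationError("affine contains non-finite values")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is singular")
    return affine


def grids_match(shape_a, affine_a, shape_b, affine_b, tol: float = AFFINE_TOL) -> bool:
    """Shapes must match exactly; affines within ``tol`` elementwise."""
    if tuple(shape_a) != tuple(shape_b):
        return False
    return bool(np.max(np.abs(np.asarray(affine_a) - np.asarray(affine_b))) <= tol)


def require_same_grid(shape_a, affine_a, shape_b, affine_b, what: str = "inputs"):
    if tuple(shape_a) != tuple(shape_b):
        raise ValidationError(f"{what}: grid shapes differ ({tuple(shape_a)} vs {tuple(shape_b)})")
    dmax = float(np.max(np.abs(np.asarray(affine_a) - np.asarray(affine_b))))
    if dmax > AFFINE_TOL:
        raise ValidationError(f"{what}: affines differ (max |delta| = {dmax:.3g} > {AFFINE_TOL})")


@dataclass
class DynamicImage:
    """4-D radioactivity volume (x, y, z, frame), decay-corrected kBq/ml."""

    voxels: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule
    unit: str = UNIT_KBQ_ML

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError(f"dynamic image must be 4-D, got ndim={self.voxels.ndim}")
        self.affine = _check_affine(self.affine)
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"image has {self.voxels.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if np.any(np.isinf(self.voxels)):
            raise ValidationError("image contains infinite values")
        if self.unit not in (UNIT_KBQ_ML, UNIT_SUV):
            raise ValidationError(f"unknown unit {self.unit!r}")

    @property
    def shape3(self) -> tuple:
        return self.voxels.shape[:3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def mean_image(self, duration_weighted: bool = True) -> np.ndarray:
        """Time-averaged 3-D image; weights are frame durations by default."""
        if duration_weighted:
            w = self.schedule.dur_min
        else:
            w = np.ones(self.schedule.n_frames)
        w = w / w.sum()
        return np.nansum(self.voxels * w[None, None, None, :], axis=3)


@dataclass
class VoxelMask:
    """Binary region on the same grid as the image it indexes."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got ndim={self.voxels.ndim}")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def volume_ml(self) -> float:
        return self.n_voxels * float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0


@dataclass
class LabelVolume:
    """Integer anatomical parcellation (FreeSurfer aseg/aparc numbering)."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"label volume must be 3-D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            as_int = np.rint(self.voxels).astype(np.int32)
            if not np.allclose(self.voxels, as_int):
                raise ValidationError("label volume must contain integer labels")
            self.voxels = as_int
        self.affine = _check_affine(self.affine)


# ---------------------------------------------------------------------------
# Time-activity curves
# ---------------------------------------------------------------------------


@dataclass
class TimeActivityCurve:
    """Regional mean activity per frame, unit-tagged."""

    t_mid: np.ndarray
    value: np.ndarray
    unit: str
    frame_dur: np.ndarray

    def __post_init__(self):
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.frame_dur = np.asarray(self.frame_dur, dtype=float)
        n = self.t_mid.size
        if not (self.value.size == n and self.frame_dur.size == n):
            raise ValidationError("t_mid, value and frame_dur must have equal length")
        if n == 0:
            raise ValidationError("empty time-activity curve")
        if not np.all(np.diff(self.t_mid) > 0):
            raise ValidationError("t_mid must be strictly increasing")
        if self.unit not in (UNIT_KBQ_ML, UNIT_SUV):
            raise ValidationError(f"unknown unit {self.unit!r}")

    @property
    def n_frames(self) -> int:
        return int(self.t_mid.size)

    def scaled(self, factor: float, unit: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            t_mid=self.t_mid.copy(),
            value=self.value * factor,
            unit=unit or self.unit,
            frame_dur=self.frame_dur.copy(),
        )


@dataclass(frozen=True)
class SubjectDose:
    """Injected dose (MBq) and body mass (kg) for SUV conversion."""

    injected_dose: float
    body_mass: float

    def __post_init__(self):
        if not (self.injected_dose > 0):
            raise ValidationError("injected_dose must be > 0")
        if not (self.body_mass > 0):
            raise ValidationError("body_mass must be > 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_tac(image: DynamicImage, mask: VoxelMask) -> TimeActivityCurve:
    """Per-frame arithmetic mean of in-mask voxels.

    NaN voxels are excluded per frame with a logged count; a frame whose
    in-mask voxels are all NaN raises an error naming the frame index.
    """
    require_same_grid(image.shape3, image.affine, mask.voxels.shape, mask.affine,
                      "image vs mask")
    if mask.n_voxels == 0:
        raise ValidationError("cannot extract a TAC from an empty mask")
    data = image.voxels[mask.voxels]  # (n_voxels, n_frames)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.info("extract_tac: excluding %d NaN voxel-frame samples", n_nan)
    n_valid = np.sum(~np.isnan(data), axis=0)
    dead = np.nonzero(n_valid == 0)[0]
    if dead.size:
        raise ValidationError(f"all in-mask voxels are NaN in frame {int(dead[0])}")
    values = np.nanmean(data, axis=0)
    return TimeActivityCurve(
        t_mid=image.schedule.mid_min,
        value=values,
        unit=image.unit,
        frame_dur=image.schedule.dur_min,
    )


def to_suv(x, dose: SubjectDose):
    """Convert kBq/ml activity to SUV (g/ml).

    SUV = value[kBq/ml] * body_mass[kg] / injected_dose[MBq]; the dimension
    check MBq/kg = kBq/g makes SUV come out in g/ml.
    """
    factor = dose.body_mass / dose.injected_dose
    if isinstance(x, TimeActivityCurve):
        if x.unit != UNIT_KBQ_ML:
            raise ValidationError(f"input already in {x.unit}; refusing double conversion")
        return x.scaled(factor, unit=UNIT_SUV)
    if isinstance(x, DynamicImage):
        if x.unit != UNIT_KBQ_ML:
            raise ValidationError(f"input already in {x.unit}; refusing double conversion")
        return DynamicImage(voxels=x.voxels * factor, affine=x.affine,
                            schedule=x.schedule, unit=UNIT_SUV)
    raise ValidationError(f"to_suv expects a TimeActivityCurve or DynamicImage, got {type(x)}")


def tac_auc(tac: TimeActivityCurve, window=None) -> float:
    """Trapezoidal area under the curve over ``window=[t0, t1]`` minutes.

    With ``window=None`` integrates over the full sampled range. Window
    endpoints falling between samples are linearly interpolated; a window
    outside the sampled range is an error.
    """
    t, v = tac.t_mid, tac.value
    if window is None:
        return float(np.trapezoid(v, t))
    t0, t1 = float(window[0]), float(window[1])
    if not t0 < t1:
        raise ValidationError(f"window must satisfy t0 < t1, got [{t0}, {t1}]")
    eps = 1e-9
    if t0 < t[0] - eps or t1 > t[-1] + eps:
        raise ValidationError(
            f"window [{t0}, {t1}] outside sampled range [{t[0]}, {t[-1]}] min")
    t0 = min(max(t0, t[0]), t[-1])
    t1 = min(max(t1, t[0]), t[-1])
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    vv = np.concatenate(([np.interp(t0, t, v)], v[inner], [np.interp(t1, t, v)]))
    return float(np.trapezoid(vv, tt))


def curve_with_zero_origin(t: np.ndarray, v: np.ndarray):
    """Prepend the (0, 0) sample used for integrals from injection time."""
    if t[0] > 0:
        return np.concatenate(([0.0], t)), np.concatenate(([0.0], v))
    return t, v
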