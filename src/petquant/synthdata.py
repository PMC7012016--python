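"""Ground-truth generators: plasma input, forward kinetic models, 4-D
phantoms with label volumes and noise, and simulated operator masks.

Forward-model frame values are interval averages (emulating scanner
binning), while the fitting code samples at frame mid-times; the induced
mismatch is part of realistic testing. All randomness flows through one
seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DynamicImage,
    FrameSchedule,
    LabelVolume,
    TimeActivityCurve,
    UNIT_KBQ_ML,
    ValidationError,
    VoxelMask,
)
from .kinetics import (
    DEFAULT_DT_SEC,
    PlasmaInput,
    expconv_uniform,
    fine_grid,
    interp_from_zero,
    tcm2_curve_fine,
    _frame_average,
    _srtm_model_fine,
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# Plasma input (triexponential bolus)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputModelParams:
    """Triexponential bolus input.

    ``C_p(t) = (A1*(t-tau) - A2 - A3) e^{lam1 (t-tau)} + A2 e^{lam2 (t-tau)}
    + A3 e^{lam3 (t-tau)}`` for ``t > tau``, else 0. Requires
    ``lam1 < lam2 < lam3 < 0``; the form guarantees ``C_p(tau) = 0``.
    """

    A1: float = 800.0   # activity / min
    A2: float = 21.9    # activity
    A3: float = 20.8    # activity
    lam1: float = -4.0  # 1/min
    lam2: float = -0.12
    lam3: float = -0.01
    delay: float = 0.5  # min

    def __post_init__(self):
        if not (self.lam1 < self.lam2 < self.lam3 < 0):
            raise ValidationError("need lam1 < lam2 < lam3 < 0")
        if self.delay < 0:
            raise ValidationError("delay must be >= 0")


def plasma_curve(params: InputModelParams, t: np.ndarray) -> PlasmaInput:
    """Evaluate the bolus model on grid ``t`` (minutes, must start at 0)."""
    t = np.asarray(t, dtype=float)
    u = t - params.delay
    cp = np.where(
        u > 0,
        (params.A1 * u - params.A2 - params.A3) * np.exp(params.lam1 * u)
        + params.A2 * np.exp(params.lam2 * u)
        + params.A3 * np.exp(params.lam3 * u),
        0.0,
    )
    if np.any(cp < -1e-9 * max(1.0, np.abs(cp).max())):
        raise ValidationError("input model parameters produce negative plasma activity")
    return PlasmaInput(t=t, cp=np.clip(cp, 0.0, None))


# ---------------------------------------------------------------------------
# Forward kinetic models (frame-averaged)
# ---------------------------------------------------------------------------


def _tac_from_fine(tf, yf, schedule: FrameSchedule) -> TimeActivityCurve:
    return TimeActivityCurve(t_mid=schedule.mid_min,
                             value=_frame_average(tf, yf, schedule),
                             unit=UNIT_KBQ_ML, frame_dur=schedule.dur_min)


def forward_1tcm(plasma: PlasmaInput, K1: float, k2: float,
                 schedule: FrameSchedule,
                 dt_sec: float = DEFAULT_DT_SEC) -> TimeActivityCurve:
    """One-tissue compartment forward model, frame-averaged."""
    if K1 < 0 or k2 < 0:
        raise ValidationError("rate constants must be >= 0")
    tf = fine_grid(schedule.end_min[-1], dt_sec)
    cpf = np.interp(tf, plasma.t, plasma.cp)
    yf = K1 * expconv_uniform(cpf, tf[1] - tf[0], k2)
    return _tac_from_fine(tf, yf, schedule)


def forward_2tcm(plasma: PlasmaInput, K1: float, k2: float, k3: float, k4: float,
                 schedule: FrameSchedule,
                 dt_sec: float = DEFAULT_DT_SEC) -> TimeActivityCurve:
    """Two-tissue compartment forward model, frame-averaged."""
    if min(K1, k2, k3, k4) < 0:
        raise ValidationError("rate constants must be >= 0")
    tf = fine_grid(schedule.end_min[-1], dt_sec)
    cpf = np.interp(tf, plasma.t, plasma.cp)
    yf = tcm2_curve_fine(cpf, tf[1] - tf[0], K1, k2, k3, k4)
    return _tac_from_fine(tf, yf, schedule)


def forward_srtm(cr: TimeActivityCurve, R1: float, k2: float, BP_ND: float,
                 schedule: FrameSchedule,
                 dt_sec: float = DEFAULT_DT_SEC) -> TimeActivityCurve:
    """SRTM operational-equation forward model, frame-averaged.

    ``cr`` may be a dense curve or a frame TAC; it must cover the schedule.
    """
    if cr.t_mid[-1] < schedule.end_min[-1] - schedule.dur_min[-1] / 2 - 1e-9:
        raise ValidationError("reference curve does not cover the schedule")
    tf = fine_grid(schedule.end_min[-1], dt_sec)
    crf = interp_from_zero(cr.t_mid, cr.value, tf)
    yf = _srtm_model_fine(crf, tf[1] - tf[0], R1, k2, BP_ND)
    return _tac_from_fine(tf, yf, schedule)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


def default_schedule(kind: str = "dynamic_90") -> FrameSchedule:
    """Canonical frame schedules for simulations and tests.

    ``dynamic_90``: dynamic scan covering the first 90 min (4x15 s, 4x30 s,
    3x60 s, 3x120 s, 3x240 s, 14x300 s; ends at 94 min so frame mid-times
    span a full [60, 90] min window). ``coarse_20``: 10 uniform 2-min frames.
    """
    if kind == "dynamic_90":
        durs = [15.0] * 4 + [30.0] * 4 + [60.0] * 3 + [120.0] * 3 + [240.0] * 3 + [300.0] * 14
    elif kind == "coarse_20":
        durs = [120.0] * 10
    else:
        raise ValidationError(f"unknown schedule kind {kind!r}")
    ends = np.cumsum(durs)
    starts = ends - np.asarray(durs)
    return FrameSchedule(starts, ends)


# ---------------------------------------------------------------------------
# Phantom builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionGeometry:
    """A sphere or box region placed on the phantom grid (voxel units)."""

    label: int
    shape: str  # "sphere" | "box"
    center: tuple
    size: float | tuple  # radius (sphere) or half-extents (box)

    def voxels(self, grid_shape) -> np.ndarray:
        idx = np.indices(grid_shape)
        c = np.asarray(self.center, dtype=float)
        if self.shape == "sphere":
            d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
            return d2 <= float(self.size) ** 2
        if self.shape == "box":
            h = np.broadcast_to(np.asarray(self.size, dtype=float), (3,))
            return np.all([np.abs(idx[i] - c[i]) <= h[i] for i in range(3)], axis=0)
        raise ValidationError(f"unknown region shape {self.shape!r}")


@dataclass
class RegionKinetics:
    """True kinetic model and parameters of one phantom region."""

    label: int
    model: str  # "srtm" | "1tcm" | "2tcm"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"srtm": {"R1", "k2", "BP_ND"},
                    "1tcm": {"K1", "k2"},
                    "2tcm": {"K1", "k2", "k3", "k4"}}
        if self.model not in required:
            raise ValidationError(f"unknown region model {self.model!r}")
        missing = required[self.model] - set(self.params)
        if missing:
            raise ValidationError(f"region {self.label}: missing params {sorted(missing)}")


@dataclass
class PhantomSpec:
    """Geometry, schedule and noise model of a synthetic dynamic scan."""

    grid_shape: tuple = (40, 40, 40)
    voxel_size_mm: float = 2.0
    regions: list = field(default_factory=list)  # RegionGeometry
    schedule: FrameSchedule | None = None
    noise: str = "none"       # "none" | "gaussian"
    noise_scale: float = 0.0  # sd = scale * sqrt(C / dt_frame)
    seed: int | None = None

    def __post_init__(self):
        if self.schedule is None:
            self.schedule = default_schedule("dynamic_90")
        if self.noise not in ("none", "gaussian"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.noise == "gaussian" and self.seed is None:
            raise ValidationError("seed is mandatory when noise != none")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        # center the grid on world origin so hemispheres are meaningful
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


def default_phantom_spec(seed: int = 0, noise_scale: float = 0.0,
                         grid_shape=(40, 40, 40),
                         ref_radius_frac: float = 0.18) -> PhantomSpec:
    """Default geometry: cerebellum-proxy sphere (label 8), two target
    spheres (17, 18), lateral-ventricle proxy boxes (4, 43) and an
    occipital-proxy box straddling the midline (1011)."""
    nx, ny, nz = grid_shape

    def c(fx, fy, fz):
        return (fx * nx, fy * ny, fz * nz)

    regions = [
        RegionGeometry(label=8, shape="sphere", center=c(0.5, 0.5, 0.28),
                       size=nx * ref_radius_frac),
        RegionGeometry(label=17, shape="sphere", center=c(0.25, 0.5, 0.70),
                       size=nx * 0.10),
        RegionGeometry(label=18, shape="sphere", center=c(0.75, 0.5, 0.70),
                       size=nx * 0.10),
        RegionGeometry(label=4, shape="box", center=c(0.42, 0.5, 0.70),
                       size=(nx * 0.03, ny * 0.08, nz * 0.08)),
        RegionGeometry(label=43, shape="box", center=c(0.58, 0.5, 0.70),
                       size=(nx * 0.03, ny * 0.08, nz * 0.08)),
        RegionGeometry(label=1011, shape="box", center=c(0.5, 0.5, 0.90),
                       size=(nx * 0.30, ny * 0.10, nz * 0.045)),
    ]
    noise = "gaussian" if noise_scale > 0 else "none"
    return PhantomSpec(grid_shape=tuple(grid_shape), regions=regions, noise=noise,
                       noise_scale=noise_scale, seed=seed)


def build_phantom(spec: PhantomSpec, ref_kinetics: RegionKinetics, targets,
                  input_params: InputModelParams | None = None):
    """Materialize a 4-D phantom.

    Returns ``(DynamicImage, LabelVolume, truth, PlasmaInput)`` where
    ``truth`` maps region label -> {"tac": noiseless frame TAC,
    "params": generating parameters, "model": name}. SRTM-based targets are
    driven by the generated reference TAC (computed densely, then
    frame-averaged). Gaussian noise has per-voxel-frame sd
    ``scale * sqrt(C / frame_duration)``.
    """
    if input_params is None:
        input_params = InputModelParams()
    schedule = spec.schedule
    affine = spec.affine()

    label_vol = np.zeros(spec.grid_shape, dtype=np.int32)
    masks = {}
    for geom in spec.regions:
        m = geom.voxels(spec.grid_shape)
        if np.any(label_vol[m] != 0):
            raise ValidationError(f"region {geom.label} overlaps an earlier region")
        label_vol[m] = geom.label
        masks[geom.label] = m
    if ref_kinetics.label not in masks:
        raise ValidationError(f"reference region label {ref_kinetics.label} missing "
                              "from phantom geometry")

    tf = fine_grid(schedule.end_min[-1])
    plasma = plasma_curve(input_params, tf)

    if ref_kinetics.model != "1tcm":
        raise ValidationError("reference region kinetics must be 1tcm "
                              "(no specific binding)")
    cr_fine = plasma.cp * 0.0
    cr_fine = ref_kinetics.params["K1"] * expconv_uniform(
        plasma.cp, tf[1] - tf[0], ref_kinetics.params["k2"])
    cr_dense = TimeActivityCurve(t_mid=tf[1:], value=cr_fine[1:], unit=UNIT_KBQ_ML,
                                 frame_dur=np.full(tf.size - 1, tf[1] - tf[0]))
    ref_tac = _tac_from_fine(tf, cr_fine, schedule)

    truth = {ref_kinetics.label: {"model": "1tcm", "params": dict(ref_kinetics.params),
                                  "tac": ref_tac}}
    region_tacs = {ref_kinetics.label: ref_tac}
    for rk in targets:
        if rk.label not in masks:
            raise ValidationError(f"target region label {rk.label} missing from geometry")
        if rk.model == "srtm":
            tac = forward_srtm(cr_dense, rk.params["R1"], rk.params["k2"],
                               rk.params["BP_ND"], schedule)
        elif rk.model == "1tcm":
            tac = forward_1tcm(plasma, rk.params["K1"], rk.params["k2"], schedule)
        else:
            tac = forward_2tcm(plasma, rk.params["K1"], rk.params["k2"],
                               rk.params["k3"], rk.params["k4"], schedule)
        truth[rk.label] = {"model": rk.model, "params": dict(rk.params), "tac": tac}
        region_tacs[rk.label] = tac

    voxels = np.zeros(spec.grid_shape + (schedule.n_frames,), dtype=float)
    for label, tac in region_tacs.items():
        voxels[masks[label]] = tac.value

    if spec.noise == "gaussian" and spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        any_region = label_vol > 0
        conc = voxels[any_region]  # (nvox, nframes)
        sd = spec.noise_scale * np.sqrt(np.clip(conc, 0.0, None)
                                        / schedule.dur_min[None, :])
        voxels[any_region] = conc + rng.normal(0.0, 1.0, conc.shape) * sd

    image = DynamicImage(voxels=voxels, affine=affine, schedule=schedule)
    labels = LabelVolume(voxels=label_vol, affine=affine)
    return image, labels, truth, plasma


# ---------------------------------------------------------------------------
# Operator-mask simulator
# ---------------------------------------------------------------------------


def simulate_operator_masks(true_region: VoxelMask, n_operators: int,
                            slice_count: int = 3, slice_jitter: float = 0.0,
                            margin: int = 0, seed: int = 0):
    """Emulate manual delineation on a few consecutive transaxial slices.

    Each operator's mask is ``slice_count`` consecutive z-slices centered
    (with seeded Gaussian jitter, sd ``slice_jitter`` slices) on the
    region's central slice, intersected with the true region eroded or
    dilated by a seeded per-operator margin drawn uniformly from
    ``[-margin, +margin]`` voxels.
    """
    if n_operators < 1:
        raise ValidationError("need at least one operator")
    z_any = np.nonzero(true_region.voxels.any(axis=(0, 1)))[0]
    if z_any.size <= slice_count:
        raise ValidationError(
            f"region spans {z_any.size} transaxial slices; need > {slice_count}")
    z_lo, z_hi = int(z_any[0]), int(z_any[-1])
    z_center = int(round(z_any.mean()))
    rng = np.random.default_rng(seed)

    out = []
    for _ in range(n_operators):
        z0 = z_center - slice_count // 2
        if slice_jitter > 0:
            z0 += int(round(rng.normal(0.0, slice_jitter)))
        z0 = int(np.clip(z0, z_lo, z_hi - slice_count + 1))
        slab = np.zeros_like(true_region.voxels)
        slab[:, :, z0:z0 + slice_count] = True

        region = true_region.voxels
        if margin > 0:
            m = int(rng.integers(-margin, margin + 1))
            if m > 0:
                region = ndimage.binary_dilation(region, _STRUCT6, iterations=m)
            elif m < 0:
                region = ndimage.binary_erosion(region, _STRUCT6, iterations=-m)
        mask = slab & region
        if not mask.any():
            raise ValidationError("simulated operator mask is empty; reduce jitter/margin")
        out.append(VoxelMask(voxels=mask, affine=true_region.affine))
    return out
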