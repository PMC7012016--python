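"""Kinetic models for dynamic PET quantification.

Regional models: SRTM (bounded nonlinear least squares), Logan and Patlak
graphical analyses with plasma or reference-tissue input, SUV ratio over a
time window, fractional uptake ratio, and the two-tissue compartment model
on regional data. Voxelwise SRTM uses the basis-function method.

Numerics: model curves are evaluated on a uniform fine time grid
(default step 0.25 s expressed in minutes) with linear interpolation of the
input curve, using the exact convolution of a piecewise-linear input with a
decaying exponential (implemented as a linear recurrence via
``scipy.signal.lfilter``), then sampled back at frame mid-times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import (
    SEC_PER_MIN,
    DynamicImage,
    FrameSchedule,
    NumericalError,
    TimeActivityCurve,
    ValidationError,
    VoxelMask,
    curve_with_zero_origin,
)

logger = logging.getLogger(__name__)

DEFAULT_DT_SEC = 0.25

# default voxelwise basis grid for the SRTM washout constant k2a (1/min)
DEFAULT_K2A_GRID = np.geomspace(0.006, 0.6, 64)

SRTM_BOUNDS = {
    "R1": (1e-6, 10.0),
    "k2": (1e-6, 5.0),
    "BP_ND": (-0.9 + 1e-9, 30.0),
}

TCM2_BOUNDS = {
    "K1": (1e-6, 3.0),
    "k2": (1e-6, 3.0),
    "k3": (0.0, 3.0),
    "k4": (0.0, 1.0),
    "V_B": (0.0, 0.5),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PlasmaInput:
    """Metabolite-corrected arterial plasma curve (minutes, kBq/ml)."""

    t: np.ndarray
    cp: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.t.ndim != 1 or self.t.size != self.cp.size:
            raise ValidationError("plasma t and cp must be 1-D and equal length")
        if self.t.size < 2:
            raise ValidationError("plasma input needs at least 2 samples")
        if abs(self.t[0]) > 1e-12:
            raise ValidationError("plasma time grid must start at 0")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("plasma time grid must be strictly increasing")
        if np.any(self.cp < -1e-12):
            raise ValidationError("plasma activity must be non-negative")
        if abs(self.cp[0]) > 1e-9 * max(1.0, self.cp.max()):
            raise ValidationError("plasma activity must be 0 at t=0")

    def cumulative_integral(self):
        """Cumulative trapezoidal integral of cp on its own grid."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.cp, self.t, initial=0.0)


@dataclass
class KineticFitResult:
    """Parameter estimates plus fit diagnostics for one regional model."""

    model: str
    params: dict
    se: dict = field(default_factory=dict)
    fitted: TimeActivityCurve | None = None
    rss: float = 0.0
    n_points: int = 0
    t_star_used: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")
        p = self.params
        if "BP_ND" in p and "DVR" in p:
            if abs(p["BP_ND"] - (p["DVR"] - 1.0)) > 1e-12:
                raise ValidationError("BP_ND must equal DVR - 1")

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "t_star_used": self.t_star_used,
            "diagnostics": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                            for k, v in self.diagnostics.items()},
        }
        return out


@dataclass
class ParametricMaps:
    """Per-parameter 3-D maps on the PET grid; non-fitted voxels are NaN."""

    maps: dict
    mask: VoxelMask
    affine: np.ndarray
    n_failed: int = 0


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------


def expconv_uniform(c: np.ndarray, dt: float, theta: float) -> np.ndarray:
    """Exact ``c(t) (*) exp(-theta t)`` for piecewise-linear ``c`` on a uniform grid.

    Solves ``y' = c - theta*y`` with ``y(0)=0`` exactly on each interval,
    vectorized as an IIR recurrence. ``theta=0`` degenerates to the running
    trapezoidal integral.
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n == 0:
        return c.copy()
    y = np.empty(n)
    y[0] = 0.0
    if n == 1:
        return y
    if theta < 1e-12:
        from scipy.integrate import cumulative_trapezoid

        y[1:] = cumulative_trapezoid(c, dx=dt)
        return y
    E = np.exp(-theta * dt)
    m = (c[1:] - c[:-1]) / dt
    b = c[:-1] * (1.0 - E) / theta + m * (dt / theta - (1.0 - E) / theta**2)
    # y[i+1] = E*y[i] + b[i]
    y[1:] = signal.lfilter([1.0], [1.0, -E], b)
    return y


def fine_grid(t_end: float, dt_sec: float = DEFAULT_DT_SEC) -> np.ndarray:
    """Uniform grid [0, >= t_end] minutes with the given step in seconds."""
    dt = dt_sec / SEC_PER_MIN
    n = int(np.ceil(t_end / dt)) + 1
    return np.arange(n + 1) * dt


def interp_from_zero(t: np.ndarray, v: np.ndarray, tf: np.ndarray) -> np.ndarray:
    """Linear interpolation with an implied (0, 0) sample prepended."""
    t0, v0 = curve_with_zero_origin(np.asarray(t, float), np.asarray(v, float))
    return np.interp(tf, t0, v0)


def _frame_average(tf: np.ndarray, yf: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (scanner binning)."""
    from scipy.integrate import cumulative_trapezoid

    F = np.concatenate(([0.0], cumulative_trapezoid(yf, tf)))
    Fs = np.interp(schedule.start_min, tf, F)
    Fe = np.interp(schedule.end_min, tf, F)
    return (Fe - Fs) / schedule.dur_min


# ---------------------------------------------------------------------------
# SRTM
# ---------------------------------------------------------------------------


def _srtm_model_fine(crf: np.ndarray, dt: float, r1: float, k2: float,
                     bp: float) -> np.ndarray:
    k2a = k2 / (1.0 + bp)
    conv = expconv_uniform(crf, dt, k2a)
    return r1 * crf + (k2 - r1 * k2a) * conv


def _check_same_frame_grid(ct: TimeActivityCurve, cr: TimeActivityCurve):
    if ct.n_frames != cr.n_frames or not np.allclose(ct.t_mid, cr.t_mid, atol=1e-9):
        raise ValidationError("target and reference TACs must share the frame grid")
    if ct.unit != cr.unit:
        raise ValidationError(f"TAC units differ: {ct.unit} vs {cr.unit}")


def srtm_fit(ct: TimeActivityCurve, cr: TimeActivityCurve, weights=None,
             dt_sec: float = DEFAULT_DT_SEC, n_starts: int = 5,
             seed: int = 0) -> KineticFitResult:
    """Simplified reference tissue model, weighted bounded NLS over (R1, k2, BP_ND).

    Model: ``C_T = R1*C_R + (k2 - R1*k2a) * C_R (*) exp(-k2a t)`` with
    ``k2a = k2/(1+BP_ND)``. Multistart (seeded) around a canonical start.
    """
    _check_same_frame_grid(ct, cr)
    if ct.n_frames < 6:
        raise ValidationError("SRTM needs at least 6 frames")
    if weights is None:
        w = np.ones(ct.n_frames)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != ct.n_frames or np.any(w < 0):
            raise ValidationError("weights must be non-negative, one per frame")
    sw = np.sqrt(w)

    tf = fine_grid(ct.t_mid[-1], dt_sec)
    dt = tf[1] - tf[0]
    crf = interp_from_zero(cr.t_mid, cr.value, tf)

    lo = np.array([SRTM_BOUNDS["R1"][0], SRTM_BOUNDS["k2"][0], SRTM_BOUNDS["BP_ND"][0]])
    hi = np.array([SRTM_BOUNDS["R1"][1], SRTM_BOUNDS["k2"][1], SRTM_BOUNDS["BP_ND"][1]])

    def resid(p):
        yf = _srtm_model_fine(crf, dt, *p)
        y = np.interp(ct.t_mid, tf, yf)
        return (y - ct.value) * sw

    rng = np.random.default_rng(seed)
    x0_base = np.array([1.0, 0.1, 1.0])
    best = None
    for i in range(max(1, n_starts)):
        if i == 0:
            x0 = x0_base
        else:
            x0 = x0_base * np.exp(rng.normal(0.0, 0.5, size=3))
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - optimizer internal failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise NumericalError("SRTM fit did not converge after multistart")

    r1, k2, bp = best.x
    rss = float(2.0 * best.cost)
    yf = _srtm_model_fine(crf, dt, r1, k2, bp)
    fitted = TimeActivityCurve(t_mid=ct.t_mid, value=np.interp(ct.t_mid, tf, yf),
                               unit=ct.unit, frame_dur=ct.frame_dur)
    se = _nls_se(best.jac, rss, ct.n_frames, 3, names=("R1", "k2", "BP_ND"))
    params = {"R1": float(r1), "k2": float(k2), "BP_ND": float(bp),
              "DVR": float(bp) + 1.0, "k2a": float(k2 / (1.0 + bp))}
    return KineticFitResult(model="srtm", params=params, se=se, fitted=fitted,
                            rss=rss, n_points=ct.n_frames)


def _nls_se(jac: np.ndarray, rss: float, n: int, p: int, names) -> dict:
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        diag = np.clip(np.diag(cov), 0.0, None)
        return {k: float(np.sqrt(d)) for k, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {}


def srtm_basis_fit(image: DynamicImage, cr: TimeActivityCurve,
                   brain_mask: VoxelMask, basis: np.ndarray | None = None,
                   dt_sec: float = DEFAULT_DT_SEC) -> ParametricMaps:
    """Voxelwise SRTM via the basis-function method.

    For each candidate washout constant ``theta`` (= k2a) the model is linear
    in the coefficients of ``{C_R, C_R (*) exp(-theta t)}``; the theta with
    the smallest residual per voxel wins, and (R1, k2, BP_ND) follow from the
    linear coefficients. Failed voxels become NaN and are counted.
    """
    from .core import require_same_grid

    require_same_grid(image.shape3, image.affine, brain_mask.voxels.shape,
                      brain_mask.affine, "image vs brain mask")
    if brain_mask.n_voxels == 0:
        raise ValidationError("brain mask is empty")
    if cr.n_frames != image.schedule.n_frames or not np.allclose(
            cr.t_mid, image.schedule.mid_min, atol=1e-9):
        raise ValidationError("reference TAC must share the image frame grid")
    thetas = DEFAULT_K2A_GRID if basis is None else np.asarray(basis, dtype=float)
    if thetas.ndim != 1 or thetas.size < 1 or np.any(thetas <= 0):
        raise ValidationError("basis grid must be 1-D with positive k2a values")

    t_mid = image.schedule.mid_min
    tf = fine_grid(t_mid[-1], dt_sec)
    dt = tf[1] - tf[0]
    crf = interp_from_zero(cr.t_mid, cr.value, tf)
    crm = np.interp(t_mid, tf, crf)

    Y = image.voxels[brain_mask.voxels]  # (nvox, nframes)
    ok = np.all(np.isfinite(Y), axis=1)
    n_failed = int((~ok).sum())
    Yt = Y[ok].T  # (nframes, nvox)
    nvox = Yt.shape[1]

    best_rss = np.full(nvox, np.inf)
    best_theta = np.zeros(nvox)
    best_c1 = np.zeros(nvox)
    best_c2 = np.zeros(nvox)
    for theta in thetas:
        bconv = np.interp(t_mid, tf, expconv_uniform(crf, dt, theta))
        A = np.column_stack([crm, bconv])  # (nframes, 2)
        coef, _, _, _ = np.linalg.lstsq(A, Yt, rcond=None)  # (2, nvox)
        resid = Yt - A @ coef
        rss = np.einsum("ij,ij->j", resid, resid)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_theta[better] = theta
        best_c1[better] = coef[0, better]
        best_c2[better] = coef[1, better]

    r1 = best_c1
    k2 = best_c2 + r1 * best_theta
    with np.errstate(divide="ignore", invalid="ignore"):
        bp = k2 / best_theta - 1.0

    shape = image.shape3
    maps = {}
    for name, vals in (("R1", r1), ("k2", k2), ("BP_ND", bp)):
        m = np.full(shape, np.nan)
        mm = np.full(nvox, np.nan)
        mm[:] = vals
        full = np.full(ok.size, np.nan)
        full[ok] = mm
        m[brain_mask.voxels] = full
        maps[name] = m
    bad = ~np.isfinite(maps["BP_ND"][brain_mask.voxels])
    n_failed = int(bad.sum())
    return ParametricMaps(maps=maps, mask=brain_mask, affine=image.affine,
                          n_failed=n_failed)


# ---------------------------------------------------------------------------
# Graphical analyses
# ---------------------------------------------------------------------------


def _cumint_tac(tac: TimeActivityCurve) -> np.ndarray:
    """Integral of the TAC from injection (0,0) to each frame mid-time."""
    from scipy.integrate import cumulative_trapezoid

    t0, v0 = curve_with_zero_origin(tac.t_mid, tac.value)
    F = cumulative_trapezoid(v0, t0, initial=0.0)
    if t0.size == tac.t_mid.size:  # no sample was prepended
        return F
    return F[1:]


def _late_points(t_mid: np.ndarray, t_star: float) -> np.ndarray:
    keep = t_mid >= t_star - 1e-9
    if keep.sum() < 3:
        raise ValidationError(
            f"need >= 3 frames with t_mid >= t_star={t_star}, got {int(keep.sum())}")
    return keep


def _ols_slope(x: np.ndarray, y: np.ndarray):
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    rss = float(np.sum((y - fitted) ** 2))
    slope, intercept = float(coef[0]), float(coef[1])
    n = x.size
    se_slope = np.nan
    if n > 2:
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx > 0:
            se_slope = float(np.sqrt(rss / (n - 2) / sxx))
    return slope, intercept, rss, se_slope


def logan_ref(ct: TimeActivityCurve, cr: TimeActivityCurve, t_star: float,
              k2prime: float | None = None) -> KineticFitResult:
    """Reference-input Logan plot; slope is DVR, BP_ND = DVR - 1.

    ``y(T) = int_0^T C_T / C_T(T)`` against
    ``x(T) = [int_0^T C_R + C_R(T)/k2'] / C_T(T)``; with ``k2prime=None`` the
    ``C_R/k2'`` term is omitted (documented simplification).
    """
    _check_same_frame_grid(ct, cr)
    keep = _late_points(ct.t_mid, t_star)
    int_ct = _cumint_tac(ct)
    int_cr = _cumint_tac(cr)
    num = int_cr + (cr.value / k2prime if k2prime else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = num / ct.value
        y = int_ct / ct.value
    x, y = x[keep], y[keep]
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise NumericalError("Logan coordinates are not finite (zero target activity?)")
    slope, intercept, rss, se_slope = _ols_slope(x, y)
    params = {"DVR": slope, "BP_ND": slope - 1.0, "intercept": intercept}
    return KineticFitResult(model="logan_ref", params=params,
                            se={"DVR": se_slope, "BP_ND": se_slope},
                            rss=rss, n_points=int(keep.sum()), t_star_used=float(t_star),
                            diagnostics={"k2prime": k2prime})


def _plasma_cumint_at(plasma: PlasmaInput, T: np.ndarray) -> np.ndarray:
    if np.any(T > plasma.t[-1] + 1e-9):
        raise ValidationError(
            f"plasma input ends at {plasma.t[-1]:.3g} min but a frame mid-time "
            f"reaches {T.max():.3g} min")
    F = plasma.cumulative_integral()
    return np.interp(T, plasma.t, F)


def logan_plasma(ct: TimeActivityCurve, plasma: PlasmaInput,
                 t_star: float) -> KineticFitResult:
    """Plasma-input Logan plot; slope is the total distribution volume V_T."""
    keep = _late_points(ct.t_mid, t_star)
    int_ct = _cumint_tac(ct)
    int_cp = _plasma_cumint_at(plasma, ct.t_mid)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = int_cp / ct.value
        y = int_ct / ct.value
    x, y = x[keep], y[keep]
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise NumericalError("Logan coordinates are not finite (zero target activity?)")
    slope, intercept, rss, se_slope = _ols_slope(x, y)
    params = {"V_T": slope, "intercept": intercept}
    return KineticFitResult(model="logan_plasma", params=params, se={"V_T": se_slope},
                            rss=rss, n_points=int(keep.sum()), t_star_used=float(t_star))


def patlak_plasma(ct: TimeActivityCurve, plasma: PlasmaInput,
                  t_star: float) -> KineticFitResult:
    """Plasma-input Patlak plot; slope is the net uptake constant K_i."""
    keep = _late_points(ct.t_mid, t_star)
    int_cp = _plasma_cumint_at(plasma, ct.t_mid)
    cp_at = np.interp(ct.t_mid, plasma.t, plasma.cp)
    if np.any(cp_at[keep] <= 0):
        raise NumericalError("plasma activity must be positive at late frame mid-times")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (int_cp / cp_at)[keep]
        y = (ct.value / cp_at)[keep]
    slope, intercept, rss, se_slope = _ols_slope(x, y)
    params = {"K_i": slope, "intercept": intercept}
    return KineticFitResult(model="patlak_plasma", params=params, se={"K_i": se_slope},
                            rss=rss, n_points=int(keep.sum()), t_star_used=float(t_star))


def patlak_ref(ct: TimeActivityCurve, cr: TimeActivityCurve,
               t_star: float) -> KineticFitResult:
    """Reference-input Patlak plot; slope in 1/min."""
    _check_same_frame_grid(ct, cr)
    keep = _late_points(ct.t_mid, t_star)
    int_cr = _cumint_tac(cr)
    if np.any(cr.value[keep] <= 0):
        raise NumericalError("reference activity must be positive at late frame mid-times")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (int_cr / cr.value)[keep]
        y = (ct.value / cr.value)[keep]
    slope, intercept, rss, se_slope = _ols_slope(x, y)
    params = {"K_i": slope, "intercept": intercept}
    return KineticFitResult(model="patlak_ref", params=params, se={"K_i": se_slope},
                            rss=rss, n_points=int(keep.sum()), t_star_used=float(t_star))


# ---------------------------------------------------------------------------
# SUVR / FUR
# ---------------------------------------------------------------------------


def suvr(ct: TimeActivityCurve, cr: TimeActivityCurve, window) -> KineticFitResult:
    """SUV ratio: AUC(target) / AUC(reference) over a time window in minutes."""
    from .core import tac_auc

    _check_same_frame_grid(ct, cr)
    auc_t = tac_auc(ct, window)
    auc_r = tac_auc(cr, window)
    if auc_r == 0:
        raise ValidationError("reference AUC is zero; SUVR undefined")
    val = auc_t / auc_r
    return KineticFitResult(model="suvr", params={"SUVR": float(val)},
                            n_points=ct.n_frames,
                            diagnostics={"window": [float(window[0]), float(window[1])],
                                         "auc_target": auc_t, "auc_reference": auc_r})


def fur(ct_late: TimeActivityCurve, plasma: PlasmaInput) -> KineticFitResult:
    """Fractional uptake ratio per late frame: C_T(T) / int_0^T C_p.

    Reports the per-frame FUR curve and their mean (units 1/min).
    """
    int_cp = _plasma_cumint_at(plasma, ct_late.t_mid)
    if np.any(int_cp <= 0):
        raise ValidationError("integrated plasma activity must be positive at each frame")
    fur_vals = ct_late.value / int_cp
    fitted = TimeActivityCurve(t_mid=ct_late.t_mid, value=fur_vals, unit=ct_late.unit,
                               frame_dur=ct_late.frame_dur)
    return KineticFitResult(model="fur", params={"FUR": float(fur_vals.mean())},
                            fitted=fitted, n_points=ct_late.n_frames,
                            diagnostics={"fur_per_frame": fur_vals.tolist()})


# ---------------------------------------------------------------------------
# Two-tissue compartment model
# ---------------------------------------------------------------------------


def tcm2_curve_fine(cpf: np.ndarray, dt: float, K1: float, k2: float, k3: float,
                    k4: float) -> np.ndarray:
    """Total tissue curve of the 2TCM via its analytic biexponential kernel."""
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    a1 = 0.5 * (s - disc)
    a2 = 0.5 * (s + disc)
    if a2 - a1 < 1e-10:
        a2 = a1 + 1e-10
    phi1 = (k3 + k4 - a1) / (a2 - a1)
    phi2 = (a2 - k3 - k4) / (a2 - a1)
    return K1 * (phi1 * expconv_uniform(cpf, dt, a1) + phi2 * expconv_uniform(cpf, dt, a2))


def tcm2_fit(ct: TimeActivityCurve, plasma: PlasmaInput, vB_mode: str = "zero",
             blood: TimeActivityCurve | None = None, weights=None,
             dt_sec: float = DEFAULT_DT_SEC, n_starts: int = 10,
             seed: int = 0) -> KineticFitResult:
    """Regional two-tissue compartment model, bounded multistart NLS.

    ``vB_mode`` is ``"zero"``, ``"fit"`` or ``"fixed:<value>"``; a whole-blood
    curve is required whenever the blood volume fraction is non-zero.
    Reports ``V_T = (K1/k2)(1 + k3/k4)`` when k4 > 0 and flags an
    irreversible fit when k4 sits at the zero bound.
    """
    if np.any(plasma.cp < 0):
        raise ValidationError("plasma activity must be non-negative")
    dt_t = np.diff(plasma.t[plasma.t <= min(5.0, plasma.t[-1])])
    if dt_t.size and dt_t.max() > 1.0 + 1e-9:
        raise ValidationError("plasma input must be sampled at least once per minute early")
    if ct.n_frames < 6:
        raise ValidationError("2TCM needs at least 6 frames")

    fit_vb = False
    vb_fixed = 0.0
    if vB_mode == "fit":
        fit_vb = True
    elif vB_mode == "zero":
        vb_fixed = 0.0
    elif vB_mode.startswith("fixed:"):
        vb_fixed = float(vB_mode.split(":", 1)[1])
    else:
        raise ValidationError(f"unknown vB_mode {vB_mode!r}")
    if (fit_vb or vb_fixed > 0) and blood is None:
        raise ValidationError("a whole-blood curve is required when V_B != 0")

    if weights is None:
        w = np.ones(ct.n_frames)
    else:
        w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    tf = fine_grid(ct.t_mid[-1], dt_sec)
    dt = tf[1] - tf[0]
    cpf = interp_from_zero(plasma.t, plasma.cp, tf)
    cbm = (np.interp(ct.t_mid, *curve_with_zero_origin(blood.t_mid, blood.value))
           if blood is not None else 0.0)

    names = ["K1", "k2", "k3", "k4"] + (["V_B"] if fit_vb else [])
    lo = np.array([TCM2_BOUNDS[n][0] for n in names])
    hi = np.array([TCM2_BOUNDS[n][1] for n in names])

    def model_at_frames(p):
        K1, k2, k3, k4 = p[:4]
        vb = p[4] if fit_vb else vb_fixed
        yf = tcm2_curve_fine(cpf, dt, K1, k2, k3, k4)
        y = np.interp(ct.t_mid, tf, yf)
        return (1.0 - vb) * y + vb * cbm

    def resid(p):
        return (model_at_frames(p) - ct.value) * sw

    rng = np.random.default_rng(seed)
    x0_base = np.array([0.1, 0.1, 0.05, 0.05] + ([0.05] if fit_vb else []))
    best = None
    for i in range(max(1, n_starts)):
        x0 = x0_base if i == 0 else x0_base * np.exp(rng.normal(0.0, 0.7, x0_base.size))
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        rss_best = None if best is None else float(2 * best.cost)
        raise NumericalError(f"2TCM fit did not converge (best rss={rss_best})")

    p = best.x
    rss = float(2.0 * best.cost)
    params = {n: float(v) for n, v in zip(names, p)}
    if not fit_vb:
        params["V_B"] = float(vb_fixed)
    # k4 below 1e-4/min is indistinguishable from irreversible on a <=2 h scan
    irreversible = params["k4"] < 1e-4
    if not irreversible:
        params["V_T"] = (params["K1"] / params["k2"]) * (1.0 + params["k3"] / params["k4"])
    fitted = TimeActivityCurve(t_mid=ct.t_mid, value=model_at_frames(p),
                               unit=ct.unit, frame_dur=ct.frame_dur)
    se = _nls_se(best.jac, rss, ct.n_frames, len(names), names)
    return KineticFitResult(model="tcm2", params=params, se=se, fitted=fitted, rss=rss,
                            n_points=ct.n_frames,
                            diagnostics={"irreversible": bool(irreversible),
                                         "vB_mode": vB_mode})


# ---------------------------------------------------------------------------
# Frame weights
# ---------------------------------------------------------------------------


def weights_from_frames(schedule: FrameSchedule, tac: TimeActivityCurve | None = None,
                        scheme: str = "uniform") -> np.ndarray:
    """Per-frame fit weights, normalized to sum to the number of frames."""
    n = schedule.n_frames
    if scheme == "uniform":
        w = np.ones(n)
    elif scheme == "duration":
        w = schedule.dur_min.copy()
    elif scheme == "duration_over_activity":
        if tac is None:
            raise ValidationError("duration_over_activity weighting needs a TAC")
        act = np.abs(tac.value)
        w = schedule.dur_min.copy()
        pos = act > 0
        if not np.all(pos):
            warnings.warn("zero-activity frames: falling back to duration-only "
                          "weight for those frames", stacklevel=2)
        w[pos] = schedule.dur_min[pos] / act[pos]
        if np.any(pos):
            # keep duration-only frames on a comparable scale
            w[~pos] = schedule.dur_min[~pos] * np.median(w[pos] / schedule.dur_min[pos])
    else:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    return w * (n / w.sum())
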