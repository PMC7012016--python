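"""Validation statistics: spatial overlap, crossed random-effects ICC,
AUC standardization, distribution descriptors/overlap, and relative bias.

The ICC comes from a two-way crossed random-effects model with intercept,
``y = mu + u_study + u_operator + e``, estimated by REML; each ICC is the
proportion of total variance attributable to one component, with negative
variance estimates clipped at zero so the ICC lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._density import half_max_bounds, kde_on_grid
from .core import NumericalError, ValidationError, VoxelMask, require_same_grid

RATER_COLUMNS = ("study", "operator", "value")


# ---------------------------------------------------------------------------
# Spatial overlap
# ---------------------------------------------------------------------------


def spatial_overlap(auto: VoxelMask, manual: VoxelMask) -> float:
    """Percent of manual voxels also in auto: 100 * |A ∩ M| / |M|.

    Asymmetric by definition; the denominator is the second argument.
    """
    require_same_grid(auto.voxels.shape, auto.affine, manual.voxels.shape,
                      manual.affine, "auto vs manual mask")
    n_manual = manual.n_voxels
    if n_manual == 0:
        raise ValidationError("manual mask is empty")
    common = int(np.sum(auto.voxels & manual.voxels))
    return 100.0 * common / n_manual


def pairwise_overlap_summary(masks) -> float:
    """Mean spatial overlap over all ordered pairs (i != j)."""
    masks = list(masks)
    if len(masks) < 2:
        raise ValidationError("need at least 2 masks for pairwise overlap")
    for i, m in enumerate(masks):
        if m.n_voxels == 0:
            raise ValidationError(f"mask {i} is empty")
    vals = [spatial_overlap(a, b)
            for i, a in enumerate(masks) for j, b in enumerate(masks) if i != j]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Rater table + ICC
# ---------------------------------------------------------------------------


def validate_rater_table(table: pd.DataFrame) -> pd.DataFrame:
    if not set(RATER_COLUMNS) <= set(table.columns):
        raise ValidationError(f"rater table needs columns {RATER_COLUMNS}")
    tab = table[list(RATER_COLUMNS)].copy()
    if tab["value"].isna().any():
        raise ValidationError("rater table contains missing values")
    if tab.duplicated(["study", "operator"]).any():
        raise ValidationError("duplicated (study, operator) rows")
    n_s = tab["study"].nunique()
    n_o = tab["operator"].nunique()
    if n_s < 2 or n_o < 2:
        raise ValidationError(
            f"ICC needs >= 2 studies and >= 2 operators (got {n_s}, {n_o})")
    counts = tab.groupby("study")["operator"].nunique()
    if counts.nunique() > 1:
        warnings.warn("unbalanced design: studies have unequal operator counts",
                      stacklevel=2)
    return tab


@dataclass
class VarianceComponents:
    """REML variance components and derived ICCs of the crossed model."""

    sigma2_study: float
    sigma2_operator: float
    sigma2_residual: float
    icc_study: float
    icc_operator: float

    def __post_init__(self):
        for name in ("sigma2_study", "sigma2_operator", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("icc_study", "icc_operator"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("sigma2_study", "sigma2_operator", "sigma2_residual",
                 "icc_study", "icc_operator")}


def _reml_neg_loglik(log_s2: np.ndarray, pre: dict) -> float:
    """REML criterion via the Woodbury identity on the q = n_s + n_o
    random-effect coefficients (V is never formed at size n x n)."""
    s2s, s2o, s2e = np.exp(log_s2)
    n, ns, no = pre["n"], pre["ns"], pre["no"]
    d = np.concatenate([np.full(ns, s2s), np.full(no, s2o)])
    rd = np.sqrt(d)
    # M = s2e I_q + D^1/2 Z'Z D^1/2  (symmetric, safe as variances -> 0)
    M = s2e * np.eye(ns + no) + (rd[:, None] * pre["ZtZ"]) * rd[None, :]
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return 1e12
    logdetV = (n - ns - no) * np.log(s2e) + 2.0 * np.sum(np.log(np.diag(L)))

    def vinv_quad(Zta, Ztb, ab):
        # a' V^-1 b = (a'b - (D^1/2 Z'a)' M^-1 (D^1/2 Z'b)) / s2e
        u = np.linalg.solve(L, rd * Zta)
        v = np.linalg.solve(L, rd * Ztb)
        return (ab - float(u @ v)) / s2e

    ytVy = vinv_quad(pre["Zty"], pre["Zty"], pre["yty"])
    xtVx = vinv_quad(pre["Zt1"], pre["Zt1"], float(n))
    xtVy = vinv_quad(pre["Zt1"], pre["Zty"], pre["sum_y"])
    if xtVx <= 0:
        return 1e12
    quad = ytVy - xtVy**2 / xtVx
    return 0.5 * (logdetV + np.log(xtVx) + quad)


def icc_components(table: pd.DataFrame) -> VarianceComponents:
    """REML estimation of the crossed two-way random-effects model.

    Negative/degenerate components are clipped at 0;
    ``icc_x = sigma2_x / (sigma2_study + sigma2_operator + sigma2_residual)``.
    """
    tab = validate_rater_table(table)
    y = tab["value"].to_numpy(float)
    studies = pd.Categorical(tab["study"]).codes
    operators = pd.Categorical(tab["operator"]).codes
    n = int(y.size)
    ns, no = int(studies.max()) + 1, int(operators.max()) + 1
    Zs = np.zeros((n, ns))
    Zs[np.arange(n), studies] = 1.0
    Zo = np.zeros((n, no))
    Zo[np.arange(n), operators] = 1.0

    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        raise ValidationError("all values identical; variance components undefined")
    # center/scale for optimizer conditioning; variances rescale by vy
    ys = (y - y.mean()) / np.sqrt(vy)

    Z = np.hstack([Zs, Zo])
    pre = {
        "n": n, "ns": ns, "no": no,
        "ZtZ": Z.T @ Z,
        "Zty": Z.T @ ys,
        "Zt1": Z.sum(axis=0),
        "yty": float(ys @ ys),
        "sum_y": float(ys.sum()),
    }
    x0 = np.log(np.array([1.0, 1.0, 1.0]) / 3.0)
    lo_b = np.log(1e-10)
    res = optimize.minimize(_reml_neg_loglik, x0, args=(pre,),
                            method="Nelder-Mead",
                            bounds=[(lo_b, 6.0)] * 3,
                            options={"xatol": 1e-9, "fatol": 1e-12,
                                     "maxiter": 4000})
    if not np.all(np.isfinite(res.x)):
        raise NumericalError("REML optimization failed for the ICC model")
    s2 = np.exp(res.x) * vy
    # clip components that collapsed onto the lower bound to exactly zero
    s2[np.exp(res.x) < 1e-8] = 0.0
    total = s2.sum()
    if total <= 0:
        raise NumericalError("total variance estimated as zero")
    return VarianceComponents(
        sigma2_study=float(s2[0]),
        sigma2_operator=float(s2[1]),
        sigma2_residual=float(s2[2]),
        icc_study=float(s2[0] / total),
        icc_operator=float(s2[1] / total),
    )


def standardize_auc(aucs: pd.DataFrame, union_mean_activity) -> pd.DataFrame:
    """Divide each study's AUC values by that study's union-mask mean activity."""
    tab = aucs.copy()
    if not set(RATER_COLUMNS) <= set(tab.columns):
        raise ValidationError(f"AUC table needs columns {RATER_COLUMNS}")
    means = dict(union_mean_activity)
    missing = set(tab["study"]) - set(means)
    if missing:
        raise ValidationError(f"no union mean activity for studies: {sorted(missing)}")
    bad = [s for s, m in means.items() if not m > 0]
    if bad:
        raise ValidationError(f"union mean activity must be > 0, bad studies: {sorted(bad)}")
    tab["value"] = tab["value"] / tab["study"].map(means)
    return tab


# ---------------------------------------------------------------------------
# Distribution descriptors
# ---------------------------------------------------------------------------


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    mode: float
    skewness: float
    fwhm_bounds: tuple

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "mode": self.mode,
                "skewness": self.skewness,
                "fwhm_bounds": [self.fwhm_bounds[0], self.fwhm_bounds[1]]}


def distribution_summary(values) -> DistributionSummary:
    """Mean, sd (n-1), KDE mode, adjusted Fisher-Pearson skewness, FWHM bounds."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ValidationError(f"need >= 100 samples for a distribution summary, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if np.ptp(v) == 0.0:  # exactly constant sample -> degenerate summary
        return DistributionSummary(mean=mean, sd=0.0, mode=float(v[0]), skewness=0.0,
                                   fwhm_bounds=(float(v[0]), float(v[0])))
    skew = float(stats.skew(v, bias=False))
    grid, dens = kde_on_grid(v)
    lower, upper, mode, _, _ = half_max_bounds(grid, dens)
    return DistributionSummary(mean=mean, sd=sd, mode=float(mode), skewness=skew,
                               fwhm_bounds=(lower, upper))


def distribution_overlap(p_samples, q_samples, n_grid: int = 512) -> float:
    """Percent overlap 100 * integral of min(p, q) of two KDE densities.

    Both densities are evaluated on one common grid spanning the pooled
    range (padded by three pooled standard deviations) and renormalized to
    integrate to 1 on that grid, which makes the measure symmetric.
    """
    p = np.asarray(p_samples, dtype=float)
    q = np.asarray(q_samples, dtype=float)
    p, q = p[np.isfinite(p)], q[np.isfinite(q)]
    if p.size < 100 or q.size < 100:
        raise ValidationError("need >= 100 samples in each distribution")
    pooled = np.concatenate([p, q])
    pad = 3.0 * pooled.std()
    lo, hi = pooled.min() - pad, pooled.max() + pad
    grid = np.linspace(lo, hi, n_grid)
    dp = stats.gaussian_kde(p, bw_method="silverman")(grid)
    dq = stats.gaussian_kde(q, bw_method="silverman")(grid)
    dp = dp / np.trapezoid(dp, grid)
    dq = dq / np.trapezoid(dq, grid)
    return float(100.0 * np.trapezoid(np.minimum(dp, dq), grid))


# ---------------------------------------------------------------------------
# Outcome comparison
# ---------------------------------------------------------------------------


def relative_bias(auto, manual_mean):
    """Percent bias 100 * (auto - manual) / manual, elementwise.

    Zero-valued manual entries yield NaN with a warning (count logged).
    Works for scalars, vectors and voxel maps alike.
    """
    a = np.asarray(auto, dtype=float)
    m = np.asarray(manual_mean, dtype=float)
    if a.shape != m.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {m.shape}")
    zero = m == 0
    n_zero = int(np.sum(zero))
    if n_zero:
        warnings.warn(f"{n_zero} zero-valued manual entries -> NaN bias", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (a - m) / m
    out = np.where(zero, np.nan, out)
    return float(out) if out.ndim == 0 else out


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; errors on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)
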