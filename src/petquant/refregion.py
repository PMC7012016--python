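"""Automatic reference-region generation.

Three chained stages: label extraction from an anatomical parcellation,
anatomical correction (morphological erosion for cerebellar cortex, a
lateral-ventricle cut for occipital cortex), and exclusion of voxels in the
tails of the in-mask radioactivity distribution (FWHM bounds of a smoothed
density of the duration-weighted mean PET image).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._density import half_max_bounds, kde_on_grid
from .core import (
    DynamicImage,
    LabelVolume,
    StageError,
    ValidationError,
    VoxelMask,
    require_same_grid,
)
from .io_formats import TracerConfig

logger = logging.getLogger(__name__)

#: below this in-mask voxel count, tail exclusion is skipped with a warning
MIN_TAIL_VOXELS = 100

# 6-connected structuring element for erosion
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class RefRegionTrace:
    """Every intermediate of the reference-region chain, for auditability."""

    mask_raw: VoxelMask
    mask_anat: VoxelMask
    mask_final: VoxelMask
    volumes_ml: dict = field(default_factory=dict)
    intensity_bounds: tuple = (float("nan"), float("nan"))
    n_excluded_low: int = 0
    n_excluded_high: int = 0
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        raw, anat, fin = self.mask_raw.voxels, self.mask_anat.voxels, self.mask_final.voxels
        if np.any(anat & ~raw):
            raise ValidationError("mask_anat must be a subset of mask_raw")
        if np.any(fin & ~anat):
            raise ValidationError("mask_final must be a subset of mask_anat")
        if not self.volumes_ml:
            self.volumes_ml = {
                "raw": self.mask_raw.volume_ml(),
                "anat": self.mask_anat.volume_ml(),
                "final": self.mask_final.volume_ml(),
            }

    def to_dict(self) -> dict:
        return {
            "volumes_ml": {k: float(v) for k, v in self.volumes_ml.items()},
            "n_voxels": {"raw": self.mask_raw.n_voxels,
                         "anat": self.mask_anat.n_voxels,
                         "final": self.mask_final.n_voxels},
            "intensity_bounds": [float(self.intensity_bounds[0]),
                                 float(self.intensity_bounds[1])],
            "n_excluded_low": int(self.n_excluded_low),
            "n_excluded_high": int(self.n_excluded_high),
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Stage 1: label extraction
# ---------------------------------------------------------------------------


def extract_label_mask(labels: LabelVolume, codes) -> VoxelMask:
    """Union of voxels whose anatomical label is in ``codes``."""
    codes = list(codes)
    if not codes:
        raise ValidationError("label code set must be non-empty")
    sel = np.isin(labels.voxels, codes)
    if not sel.any():
        raise ValidationError(f"no voxel carries any of the labels {sorted(codes)}")
    return VoxelMask(voxels=sel, affine=labels.affine)


# ---------------------------------------------------------------------------
# Stage 2: anatomical correction
# ---------------------------------------------------------------------------


def anat_correct_erode(mask: VoxelMask, depth_voxels: int = 1) -> VoxelMask:
    """Peel the outermost voxels: 6-connected erosion applied ``depth`` times."""
    if depth_voxels < 1:
        raise ValidationError("erosion depth must be >= 1")
    eroded = ndimage.binary_erosion(mask.voxels, structure=_STRUCT6,
                                    iterations=depth_voxels)
    if not eroded.any():
        raise ValidationError(
            f"erosion with depth {depth_voxels} emptied the mask; use a smaller depth")
    return VoxelMask(voxels=eroded, affine=mask.affine)


def _world_x(mask_voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask_voxels)
    homog = np.column_stack([idx, np.ones(len(idx))])
    return (homog @ affine.T)[:, 0]


def anat_correct_lateral_cut(mask: VoxelMask, ventricles: VoxelMask,
                             affine: np.ndarray | None = None) -> VoxelMask:
    """Remove mask voxels lateral to the lateral ventricles, per hemisphere.

    For each hemisphere (RAS world x < 0 left, x > 0 right) the maximal
    |world x| over that hemisphere's ventricle voxels is the cut-off; mask
    voxels of the same hemisphere with strictly greater |world x| are removed.
    An empty ventricle hemisphere falls back to the global maximum with a
    warning.
    """
    if affine is None:
        affine = mask.affine
    require_same_grid(mask.voxels.shape, mask.affine, ventricles.voxels.shape,
                      ventricles.affine, "mask vs ventricles")
    if not ventricles.voxels.any():
        raise ValidationError("ventricle mask is empty")

    vx = _world_x(ventricles.voxels, affine)
    global_cut = float(np.max(np.abs(vx)))
    cuts = {}
    for hemi, sel in (("left", vx < 0), ("right", vx > 0)):
        if sel.any():
            cuts[hemi] = float(np.max(np.abs(vx[sel])))
        else:
            warnings.warn(f"no ventricle voxels in {hemi} hemisphere; "
                          "falling back to global max |x|", stacklevel=2)
            cuts[hemi] = global_cut

    idx = np.argwhere(mask.voxels)
    homog = np.column_stack([idx, np.ones(len(idx))])
    wx = (homog @ affine.T)[:, 0]
    cut = np.where(wx < 0, cuts["left"], cuts["right"])
    keep = np.abs(wx) <= cut  # strict inequality removes, ties kept
    out = np.zeros_like(mask.voxels)
    kept_idx = idx[keep]
    out[kept_idx[:, 0], kept_idx[:, 1], kept_idx[:, 2]] = True
    if not out.any():
        raise ValidationError("lateral cut removed every mask voxel")
    return VoxelMask(voxels=out, affine=mask.affine)


# ---------------------------------------------------------------------------
# Stage 3: radioactivity tail exclusion
# ---------------------------------------------------------------------------


def tail_exclusion(mask: VoxelMask, mean_pet: np.ndarray):
    """Exclude voxels outside the FWHM bounds of the in-mask intensity density.

    ``mean_pet`` is the duration-weighted mean over frames. A smoothed
    density (Gaussian KDE, Silverman bandwidth, 512-point grid) of the
    in-mask intensities is computed; the bounds are the half-maximum
    crossings nearest the mode on each side. Voxels with
    ``lower <= intensity <= upper`` are kept (closed interval).

    Returns ``(mask_out, (lower, upper), n_excluded_low, n_excluded_high,
    warnings_list)``. Masks below ``MIN_TAIL_VOXELS`` voxels are returned
    unchanged with a warning.
    """
    mean_pet = np.asarray(mean_pet, dtype=float)
    if mean_pet.shape != mask.voxels.shape:
        raise ValidationError("mean PET image and mask shapes differ")
    warns: list[str] = []
    vals = mean_pet[mask.voxels]
    finite = np.isfinite(vals)
    if mask.n_voxels < MIN_TAIL_VOXELS:
        msg = (f"mask has {mask.n_voxels} voxels (< {MIN_TAIL_VOXELS}); "
               "skipping tail exclusion")
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
        lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
        return mask, (lo, hi), 0, 0, warns

    sample = vals[finite]
    if np.ptp(sample) == 0:
        v = float(sample[0])
        return mask, (v, v), 0, 0, warns

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        grid, dens = kde_on_grid(sample)
        lower, upper, _mode, fell_low, fell_high = half_max_bounds(grid, dens)
        warns.extend(str(w.message) for w in caught)

    inside = (vals >= lower) & (vals <= upper)
    inside &= finite  # NaN voxels always excluded here
    n_low = int(np.sum(finite & (vals < lower)))
    n_high = int(np.sum(finite & (vals > upper)))

    out = np.zeros_like(mask.voxels)
    idx = np.argwhere(mask.voxels)
    kept = idx[inside]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    if not out.any():
        raise ValidationError("tail exclusion removed every mask voxel")
    return VoxelMask(voxels=out, affine=mask.affine), (lower, upper), n_low, n_high, warns


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def generate_reference_region(labels: LabelVolume, pet: DynamicImage,
                              cfg: TracerConfig,
                              ventricles: VoxelMask | None = None) -> RefRegionTrace:
    """Label extraction -> anatomical correction -> tail exclusion.

    The anatomical correction is chosen by ``cfg.anatomical_correction``
    (erosion for cerebellar cortex, lateral ventricle cut for occipital
    cortex, or none). The ventricle mask for the lateral cut is extracted
    from ``labels`` via ``cfg.ventricle_labels`` unless given explicitly.
    Errors are re-raised labeled with the failing stage.
    """
    require_same_grid(pet.shape3, pet.affine, labels.voxels.shape, labels.affine,
                      "PET vs labels")
    all_warnings: list[str] = []

    try:
        mask_raw = extract_label_mask(labels, cfg.reference_labels)
    except Exception as exc:
        raise StageError("label_extraction", exc) from exc

    try:
        if cfg.anatomical_correction == "erode":
            mask_anat = anat_correct_erode(mask_raw, cfg.erosion_depth)
        elif cfg.anatomical_correction == "lateral_cut":
            if ventricles is None:
                ventricles = extract_label_mask(labels, cfg.ventricle_labels)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mask_anat = anat_correct_lateral_cut(mask_raw, ventricles, pet.affine)
            all_warnings.extend(str(w.message) for w in caught)
        else:  # "none"
            mask_anat = VoxelMask(voxels=mask_raw.voxels.copy(), affine=mask_raw.affine)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("anatomical_correction", exc) from exc

    bounds = (float("nan"), float("nan"))
    n_low = n_high = 0
    if cfg.tail_exclusion:
        try:
            mean_pet = pet.mean_image(duration_weighted=True)
            mask_final, bounds, n_low, n_high, warns = tail_exclusion(mask_anat, mean_pet)
            all_warnings.extend(warns)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("tail_exclusion", exc) from exc
    else:
        mask_final = VoxelMask(voxels=mask_anat.voxels.copy(), affine=mask_anat.affine)

    logger.info("reference region: raw=%d anat=%d final=%d voxels",
                mask_raw.n_voxels, mask_anat.n_voxels, mask_final.n_voxels)
    return RefRegionTrace(mask_raw=mask_raw, mask_anat=mask_anat, mask_final=mask_final,
                          intensity_bounds=bounds, n_excluded_low=n_low,
                          n_excluded_high=n_high, warnings=all_warnings)
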