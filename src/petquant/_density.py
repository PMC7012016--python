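"""Shared smoothed-density helpers (KDE settings used by refregion and evalstats).

Settings: Gaussian kernel density with Silverman bandwidth, evaluated on a
512-point grid spanning the sample range. Half-maximum crossings are located
by linear interpolation between grid points.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

N_GRID = 512


def kde_on_grid(values: np.ndarray, n_grid: int = N_GRID, lo: float | None = None,
                hi: float | None = None):
    """Gaussian KDE (Silverman bandwidth) of ``values`` on a regular grid.

    Returns ``(grid, density)``. Degenerate (constant) samples return a
    one-point grid with density 1.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values for density estimation")
    vmin = values.min() if lo is None else lo
    vmax = values.max() if hi is None else hi
    if vmax <= vmin:
        return np.array([vmin]), np.array([1.0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(vmin, vmax, n_grid)
    return grid, kde(grid)


def half_max_bounds(grid: np.ndarray, density: np.ndarray):
    """FWHM-style bounds of a smoothed density.

    Locates the mode, then the nearest half-maximum crossing on each side
    (linearly interpolated). If the density never falls to half the modal
    density on one side, the grid extreme is used on that side and a
    warning flag is set.

    Returns ``(lower, upper, mode_x, fell_back_low, fell_back_high)``.
    """
    if grid.size == 1:
        return float(grid[0]), float(grid[0]), float(grid[0]), False, False
    i_mode = int(np.argmax(density))
    half = density[i_mode] / 2.0
    mode_x = float(grid[i_mode])

    lower, fell_low = float(grid[0]), True
    for i in range(i_mode, 0, -1):
        if density[i - 1] <= half:
            # interpolate between grid[i-1] (below half) and grid[i]
            d0, d1 = density[i - 1], density[i]
            frac = (half - d0) / (d1 - d0) if d1 != d0 else 0.0
            lower = float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))
            fell_low = False
            break

    upper, fell_high = float(grid[-1]), True
    for i in range(i_mode, grid.size - 1):
        if density[i + 1] <= half:
            d0, d1 = density[i], density[i + 1]
            frac = (d0 - half) / (d0 - d1) if d0 != d1 else 0.0
            upper = float(grid[i] + frac * (grid[i + 1] - grid[i]))
            fell_high = False
            break

    if fell_low:
        warnings.warn("density has no half-max crossing below the mode; "
                      "using distribution minimum", stacklevel=2)
    if fell_high:
        warnings.warn("density has no half-max crossing above the mode; "
                      "using distribution maximum", stacklevel=2)
    return lower, upper, mode_x, fell_low, fell_high
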