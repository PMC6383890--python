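"""WASSR B0 mapping via the maximum-symmetry algorithm, plus the B0 QC gate.

A WASSR acquisition saturates weakly (0.1 uT, 0.5 s) over a narrow offset
range, so each voxel's z-spectrum is dominated by the direct-saturation dip
of water. The dip is symmetric about the voxel's true water frequency; the
maximum-symmetry estimator finds the center c minimizing the mean squared
difference between the spline-interpolated spectrum and its mirror image
about c, evaluated only over the symmetric overlap that stays inside the
sampled range. A coarse candidate grid (0.005 ppm) is refined by a parabolic
fit through the minimum and its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import B0Map, CestStack, ConfigurationError, RoiSpec, ZSpectrum
from .zspec import normalize_stack

__all__ = ["fit_voxel_shift", "build_b0_map", "qc_roi_pair", "B0QcResult"]

#: spacing of the dense interpolation grid for the symmetry search, ppm
DENSE_STEP = 0.001
#: spacing of the coarse candidate-center grid, ppm
COARSE_STEP = 0.005
#: minimum number of dense points in the mirror overlap for a usable MSE
MIN_OVERLAP = 25


def _dense_grid(offsets: np.ndarray) -> np.ndarray:
    lo = np.ceil(offsets[0] / DENSE_STEP - 1e-9)
    hi = np.floor(offsets[-1] / DENSE_STEP + 1e-9)
    return np.arange(lo, hi + 0.5) * DENSE_STEP


def _fit_shifts_dense(
    dense: np.ndarray, table: np.ndarray, search_range: float
) -> np.ndarray:
    """Maximum-symmetry centers for each column of ``table`` (n_dense, n_vox).

    Returns NaN for columns whose MSE minimum sits on the search boundary or
    whose data are non-finite.
    """
    n_dense, n_vox = table.shape
    step = DENSE_STEP
    stride = max(1, int(round(COARSE_STEP / step)))
    # candidate centers on the dense grid, limited to +/-search_range
    idx_all = np.arange(0, n_dense, stride)
    centers = dense[idx_all]
    keep = np.abs(centers) <= search_range + 1e-12
    idx_all = idx_all[keep]
    if idx_all.size < 3:
        return np.full(n_vox, np.nan)

    mse = np.full((idx_all.size, n_vox), np.inf)
    for j, ic in enumerate(idx_all):
        m = min(ic, n_dense - 1 - ic)
        if m < MIN_OVERLAP:
            continue
        right = table[ic + 1 : ic + m + 1]
        left = table[ic - m : ic][::-1]
        d = right - left
        mse[j] = np.mean(d * d, axis=0)

    finite_cols = np.all(np.isfinite(table), axis=0)
    jmin = np.argmin(mse, axis=0)
    shifts = np.full(n_vox, np.nan)
    interior = (jmin > 0) & (jmin < idx_all.size - 1) & finite_cols
    interior &= np.isfinite(mse[jmin, np.arange(n_vox)])
    if np.any(interior):
        cols = np.nonzero(interior)[0]
        j = jmin[cols]
        y0 = mse[j - 1, cols]
        y1 = mse[j, cols]
        y2 = mse[j + 1, cols]
        denom = y0 - 2.0 * y1 + y2
        frac = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        frac = np.clip(frac, -1.0, 1.0)
        shifts[cols] = dense[idx_all[j]] + frac * stride * step
    return shifts


def fit_voxel_shift(spectrum: ZSpectrum, search_range: float = 0.3) -> float:
    """Water-frequency shift (ppm) of one WASSR spectrum.

    Returns NaN when the symmetry-MSE minimum falls on the search boundary
    (no interior optimum) or the spectrum contains non-finite values.
    """
    if len(spectrum) < 7:
        raise ConfigurationError("WASSR fit needs at least 7 offsets")
    if search_range <= 0:
        raise ConfigurationError("search range must be positive")
    if np.any(~np.isfinite(spectrum.values)):
        return float("nan")
    dense = _dense_grid(spectrum.offsets)
    cs = CubicSpline(spectrum.offsets, spectrum.values, bc_type="natural")
    table = cs(dense)[:, None]
    return float(_fit_shifts_dense(dense, table, search_range)[0])


def build_b0_map(
    wassr: CestStack,
    mask: np.ndarray | None = None,
    search_range: float = 0.3,
    intensity_threshold: float = 0.0,
    chunk: int = 4096,
) -> B0Map:
    """Voxelwise maximum-symmetry B0 map from a WASSR stack.

    The stack is normalized by its reference; voxels outside ``mask`` (or
    below the intensity threshold) are invalid, as are voxels whose estimate
    hits the search boundary.
    """
    norm, ref_mask = normalize_stack(wassr, intensity_threshold)
    if mask is None:
        mask = ref_mask
    else:
        mask = np.asarray(mask, dtype=bool) & ref_mask
    if not np.any(mask):
        raise ConfigurationError("empty mask: no voxels to fit")

    offs = wassr.offsets_ppm
    order = np.argsort(offs)
    offs = offs[order]
    if offs.size < 7:
        raise ConfigurationError("WASSR fit needs at least 7 offsets")
    dense = _dense_grid(offs)
    flat = norm[order].reshape(offs.size, -1)
    vox = np.nonzero(mask.ravel())[0]
    shifts_flat = np.full(flat.shape[1], np.nan)
    for start in range(0, vox.size, chunk):
        cols = vox[start : start + chunk]
        block = flat[:, cols]
        cs = CubicSpline(offs, block, axis=0, bc_type="natural")
        shifts_flat[cols] = _fit_shifts_dense(dense, cs(dense), search_range)
    shift = shifts_flat.reshape(wassr.shape)
    valid = np.isfinite(shift) & mask
    return B0Map(shift=shift, valid=valid)


@dataclass(frozen=True)
class B0QcResult:
    """Outcome of the between-ROI B0 homogeneity gate."""

    passed: bool
    difference_ppm: float
    threshold_ppm: float
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def qc_roi_pair(
    b0: B0Map,
    roi_a: RoiSpec,
    roi_b: RoiSpec,
    geometry,
    threshold_ppm: float = 0.05,
    statistic: str = "mean",
) -> B0QcResult:
    """Gate a subject on the B0 difference between two ROIs.

    The subject passes when the absolute difference between the ROI-average
    shifts does not exceed ``threshold_ppm`` (study gate: 0.05 ppm). An ROI
    with no valid voxel makes the comparison unmeasurable and fails.
    """
    agg = np.nanmean if statistic == "mean" else np.nanmedian
    means = []
    for roi in (roi_a, roi_b):
        rows, cols = roi.to_slices(geometry)
        block = b0.shift[rows, cols]
        ok = b0.valid[rows, cols]
        if not np.any(ok):
            return B0QcResult(False, float("nan"), threshold_ppm, "unmeasurable")
        means.append(float(agg(block[ok])))
    diff = abs(means[0] - means[1])
    return B0QcResult(diff <= threshold_ppm, diff, threshold_ppm)
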