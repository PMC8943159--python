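"""Desk-scale preprocessing: confound expansion, nuisance regression,
DVARS scrubbing, anisotropic smoothing and the seed-ventricle diagnostic.

The pipeline order is fixed: scrub -> nuisance regression -> smoothing.
Brain extraction, slice timing, realignment, ICA-based denoising and all
registration steps are out of scope; their effect on the data is emulated
upstream by the synthetic generator's confound structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "build_confounds",
    "nuisance_regress",
    "dvars_scrub",
    "ellipsoid_smooth",
    "seed_ventricle_correlation",
]

ROI_COLUMNS = ("roi_ventricle_4th", "roi_lateral_ventricles", "roi_white_matter")


def build_confounds(roi_means: pd.DataFrame, motion6) -> pd.DataFrame:
    """Assemble the 30-column nuisance regressor set.

    3 ROI mean series (4th ventricle, lateral ventricles, white matter) +
    6 motion parameters + their 6 backward-difference derivatives (leading
    element 0) + the squares of all 15 preceding series.
    """
    missing = [c for c in ROI_COLUMNS if c not in roi_means.columns]
    if missing:
        raise ValueError(f"missing ROI series: {missing}")
    motion = np.asarray(motion6, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion series, got shape {motion.shape}")
    if len(motion) != len(roi_means):
        raise ValueError("ROI and motion series lengths differ")
    out = pd.DataFrame({c: roi_means[c].to_numpy(dtype=float)
                        for c in ROI_COLUMNS})
    for i in range(6):
        out[f"motion_{i + 1}"] = motion[:, i]
    for i in range(6):
        d = np.diff(motion[:, i], prepend=motion[0, i])
        out[f"motion_{i + 1}_derivative"] = d
    for col in list(out.columns):
        out[f"{col}_sq"] = out[col] ** 2
    assert out.shape[1] == 30
    return out


def nuisance_regress(Y, confounds) -> np.ndarray:
    """Remove nuisance structure from every voxel series by OLS.

    ``Y`` may be 2-D ``(n_volumes, n_voxels)`` or 4-D ``(x, y, z, t)``.  An
    intercept is added to the confound matrix; residuals are orthogonal to
    all confound columns.
    """
    X = np.asarray(confounds, dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [j for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(
            f"confound matrix is rank deficient; dependent columns {bad} "
            "(0 is the intercept)")
    Y = np.asarray(Y, dtype=float)
    four_d = Y.ndim == 4
    if four_d:
        shape = Y.shape
        Y2 = Y.reshape(-1, shape[-1]).T  # (t, voxels)
    else:
        Y2 = Y
    beta, _, _, _ = np.linalg.lstsq(X, Y2, rcond=None)
    resid = Y2 - X @ beta
    if four_d:
        resid = resid.T.reshape(shape)
    return resid


def dvars_scrub(Y, threshold_rule: str | float = "iqr", mask=None):
    """DVARS series and the volumes retained under the scrubbing rule.

    ``dvars(t) = sqrt(mean over in-mask voxels of (Y_t - Y_{t-1})^2)`` for
    ``t = 2..N`` (length ``N - 1``).  The default rule flags volumes whose
    DVARS exceeds the 75th percentile + 1.5 IQR of the run's DVARS series;
    a float gives an absolute threshold instead.  A flagged difference
    removes the later volume of the pair.

    Returns
    -------
    dvars : ndarray, length ``N - 1``
    retained : ndarray of int
        Indices of retained volumes (design rows must be subset identically).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 4:
        if mask is None:
            mask = np.ones(Y.shape[:3], dtype=bool)
        if not np.any(mask):
            raise ValueError("empty mask")
        series = Y[mask]  # (voxels, t)
    else:
        series = Y.T
        if series.size == 0:
            raise ValueError("empty data")
    n = series.shape[1]
    if n < 2:
        raise ValueError("need at least 2 volumes")
    diff = np.diff(series, axis=1)
    dvars = np.sqrt(np.mean(diff**2, axis=0))
    if isinstance(threshold_rule, str):
        if threshold_rule != "iqr":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        q1, q3 = np.percentile(dvars, [25, 75])
        thr = q3 + 1.5 * (q3 - q1)
    else:
        thr = float(threshold_rule)
    flagged = np.flatnonzero(dvars > thr) + 1  # the later volume of each pair
    retained = np.setdiff1d(np.arange(n), flagged)
    return dvars, retained


def ellipsoid_smooth(volume4d, fwhm_xyz_mm, voxel_size_mm) -> np.ndarray:
    """Separable anisotropic (ellipsoid) Gaussian smoothing.

    An axis-aligned Gaussian with per-axis FWHM in mm enhances detection of
    elongated structures (e.g. the brainstem's rostrocaudal axis) when the
    long axis of the kernel follows the structure.  The kernel has unit
    mass, so constant images are preserved exactly.

    ``volume4d`` may be 3-D or 4-D (smoothing applies per volume).
    """
    fwhm = np.asarray(fwhm_xyz_mm, dtype=float)
    vox = np.asarray(voxel_size_mm, dtype=float)
    if fwhm.shape != (3,) or vox.shape != (3,):
        raise ValueError("fwhm_xyz_mm and voxel_size_mm must have 3 entries")
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    if np.any(sigma_vox < 0.1 / 2.3548):
        raise ValueError("FWHM below 0.1 voxel gives a degenerate kernel")
    data = np.asarray(volume4d, dtype=float)
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma_vox, mode="nearest")
    if data.ndim != 4:
        raise ValueError("expected a 3-D or 4-D array")
    out = np.empty_like(data)
    for t in range(data.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(data[..., t], sigma_vox,
                                              mode="nearest")
    return out


def seed_ventricle_correlation(seed_ts, ventricle_ts) -> float:
    """Pearson correlation between seed and 4th-ventricle series.

    A partial-volume diagnostic: high correlation suggests the seed ROI is
    contaminated by CSF signal from the adjacent ventricle.
    """
    a = np.asarray(seed_ts, dtype=float)
    b = np.asarray(ventricle_ts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series")
    return float(stats.pearsonr(a, b).statistic)
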