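"""Condition-specific HRF estimation via orthonormal basis expansion.

The BOLD series of a run is modelled as the sum of two parallel FIR systems,
one per condition (novelty / repetition), each driven by its block indicator
series.  Writing the two HRFs in an orthonormal spherical-Laguerre basis
turns the deconvolution into a small ordinary least-squares problem

    y(n) = sum_j c_1j (x_1 * b_1j)(n) + sum_j c_2j (x_2 * b_2j)(n) + e(n)

whose regressors ``v_ij = x_i * b_ij`` are the condition series convolved
with the basis columns.  The basis hyper-parameters ``(alpha, tau)`` are
chosen per subject by minimizing a leave-one-run-out cross-validated
generalization error over a grid, and the model order ``L`` by BIC; the
recommended estimation is two-step — hyper-parameters from ROI-average
series, voxel-wise coefficients with the selected basis.

Multi-run fits demean each run (response and regressors) and share the
expansion coefficients across runs, which absorbs per-run offsets without
explicit intercept columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet, build_basis
from .simulate import TaskDesign

__all__ = [
    "ExpansionFit",
    "HrfEstimate",
    "GroupHrfShape",
    "build_expansion_design",
    "fit_bold_model",
    "reconstruct_hrf",
    "cv_generalization_error",
    "grid_search_basis",
    "select_model_order",
    "hrf_summaries",
    "group_hrf_shape",
    "HrfBasisModel",
    "HrfBasisResults",
]


def convolve_to_length(x: np.ndarray, kernel: np.ndarray, n: int) -> np.ndarray:
    """Causal convolution truncated to ``n`` samples."""
    return np.convolve(x, kernel)[:n]


def build_expansion_design(design: TaskDesign, basis_nov: BasisSet,
                           basis_rep: BasisSet, intercept: bool = True):
    """Regressor matrix ``V`` for one run.

    Columns are ``x_i * b_ij`` for each condition and basis function, plus a
    trailing intercept column when ``intercept`` is true.

    Returns
    -------
    V : ndarray of shape ``(n_volumes, L1 + L2 [+ 1])``
    slices : dict
        Column slices ``{"novelty": ..., "repetition": ...}``.
    """
    for b in (basis_nov, basis_rep):
        if abs(b.dt - design.tr_seconds) > 1e-9:
            raise ValueError(
                f"basis dt {b.dt} does not match design TR {design.tr_seconds}")
    n = design.n_volumes
    cols = [convolve_to_length(design.x1, basis_nov.B[:, j], n)
            for j in range(basis_nov.L)]
    cols += [convolve_to_length(design.x2, basis_rep.B[:, j], n)
             for j in range(basis_rep.L)]
    slices = {"novelty": slice(0, basis_nov.L),
              "repetition": slice(basis_nov.L, basis_nov.L + basis_rep.L)}
    if intercept:
        cols.append(np.ones(n))
    return np.column_stack(cols), slices


@dataclass(frozen=True)
class ExpansionFit:
    """OLS fit of the basis-expansion BOLD model."""

    c: np.ndarray
    residuals: np.ndarray
    mse: float
    bic: float
    V: np.ndarray
    slices: dict

    def coef(self, condition: str) -> np.ndarray:
        return self.c[self.slices[condition]]


def fit_bold_model(y: np.ndarray, V: np.ndarray,
                   slices: dict | None = None) -> ExpansionFit:
    """Estimate expansion coefficients by ordinary least squares.

    ``BIC = N ln(RSS/N) + p ln N`` with ``p`` the number of columns of ``V``.

    Raises
    ------
    ValueError
        If ``V`` is rank deficient (names the collinear columns).
    """
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    if y.shape[0] != V.shape[0]:
        raise ValueError("y and V have incompatible lengths")
    n, p = V.shape
    rank = np.linalg.matrix_rank(V)
    if rank < p:
        # name columns whose removal restores full rank
        bad = [j for j in range(p)
               if np.linalg.matrix_rank(np.delete(V, j, axis=1)) == rank]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    c, _, _, _ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ c
    rss = float(resid @ resid)
    mse = rss / n
    bic = n * np.log(max(mse, np.finfo(float).tiny)) + p * np.log(n)
    return ExpansionFit(c=c, residuals=resid, mse=mse, bic=bic, V=V,
                        slices=slices or {})


@dataclass(frozen=True)
class HrfEstimate:
    """A sampled HRF with its shape summaries."""

    h: np.ndarray
    dt: float
    condition: str
    amplitude: float
    peak_latency: float
    fwhm: float

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.h)) * self.dt


def hrf_summaries(h: np.ndarray, dt: float):
    """``(amplitude, peak_latency, fwhm)`` of a sampled curve.

    Amplitude is the signed value at the extremum of largest magnitude (so
    inverted responses report a negative peak), latency its time, and FWHM
    the width of that lobe at half the peak magnitude with linear
    interpolation between samples.
    """
    h = np.asarray(h, dtype=float)
    if np.allclose(h, h[0]):
        raise ValueError("constant curve has no peak")
    idx = int(np.argmax(np.abs(h)))
    amplitude = float(h[idx])
    latency = idx * dt
    sgn = np.sign(amplitude)
    g = sgn * h  # peak lobe is positive in g
    half = abs(amplitude) / 2.0

    def cross(direction: int) -> float:
        i = idx
        while 0 <= i + direction < len(g) and g[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(g):
            return float(i)  # lobe truncated at the boundary
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (g[i] - half) / (g[i] - g[j])
        return i + direction * frac

    fwhm = (cross(+1) - cross(-1)) * dt
    return amplitude, float(latency), float(fwhm)


def reconstruct_hrf(fit: ExpansionFit, basis: BasisSet,
                    condition: str) -> HrfEstimate:
    """Rebuild the sampled HRF ``h = B c`` for one condition."""
    if condition not in fit.slices:
        raise KeyError(f"unknown condition {condition!r}")
    c = fit.coef(condition)
    h = basis.B @ c
    if np.allclose(h, 0):
        return HrfEstimate(h=h, dt=basis.dt, condition=condition,
                           amplitude=0.0, peak_latency=0.0, fwhm=0.0)
    amp, lat, fwhm = hrf_summaries(h, basis.dt)
    return HrfEstimate(h=h, dt=basis.dt, condition=condition,
                       amplitude=amp, peak_latency=lat, fwhm=fwhm)


# ---------------------------------------------------------------------------
# multi-run fitting, cross-validation, hyper-parameter selection


def _demeaned_design(y, design, basis_nov, basis_rep, sample_mask=None):
    V, slices = build_expansion_design(design, basis_nov, basis_rep,
                                       intercept=False)
    y = np.asarray(y, dtype=float)
    if sample_mask is not None:
        V = V[sample_mask]
        y = y[sample_mask]
    Vd = V - V.mean(axis=0)
    yd = y - y.mean()
    return yd, Vd, slices


def _stacked_fit(y_set, design_set, basis_nov, basis_rep,
                 sample_masks=None) -> ExpansionFit:
    ys, Vs, slices = [], [], None
    masks = sample_masks or [None] * len(y_set)
    for y, d, m in zip(y_set, design_set, masks):
        yd, Vd, slices = _demeaned_design(y, d, basis_nov, basis_rep, m)
        ys.append(yd)
        Vs.append(Vd)
    return fit_bold_model(np.concatenate(ys), np.vstack(Vs), slices)


def cv_generalization_error(y_set, design_set, L: int, alpha: float,
                            tau: float, memory_s: float = 24.0,
                            sigma: float = 1.0, sample_masks=None) -> float:
    """Leave-one-run-out cross-validated generalization error.

    For each fold, the expansion is fitted on the remaining runs and the
    mean squared prediction error ``mse = (1/N) sum (y_hat - y)^2`` is
    evaluated on the (demeaned) held-out run; the fold errors are averaged.
    """
    n_runs = len(y_set)
    if n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    dt = design_set[0].tr_seconds
    M = int(round(memory_s / dt))
    basis = build_basis(L, M, alpha, tau, sigma, dt)
    masks = sample_masks or [None] * n_runs
    errs = []
    for k in range(n_runs):
        train_y = [y for i, y in enumerate(y_set) if i != k]
        train_d = [d for i, d in enumerate(design_set) if i != k]
        train_m = [m for i, m in enumerate(masks) if i != k]
        fit = _stacked_fit(train_y, train_d, basis, basis, train_m)
        yd, Vd, _ = _demeaned_design(y_set[k], design_set[k], basis, basis,
                                     masks[k])
        pred = Vd @ fit.c
        errs.append(float(np.mean((pred - yd) ** 2)))
    return float(np.mean(errs))


DEFAULT_ALPHA_GRID = tuple(np.arange(0.25, 3.01, 0.25))
DEFAULT_TAU_GRID = tuple(np.arange(0.0, 4.01, 0.5))


def grid_search_basis(y_roi_set, design_set, L: int = 2,
                      alpha_grid=DEFAULT_ALPHA_GRID,
                      tau_grid=DEFAULT_TAU_GRID,
                      memory_s: float = 24.0):
    """Grid search of ``(alpha, tau)`` on the ROI-averaged CV error.

    Parameters
    ----------
    y_roi_set : sequence of sequences
        ``y_roi_set[r][k]`` is the series of ROI ``r`` in run ``k``.

    Returns
    -------
    alpha_star, tau_star : float
        The grid point minimizing the error averaged over ROIs; exact ties
        are broken by smaller ``tau`` then smaller ``alpha``.
    surface : ndarray of shape ``(len(alpha_grid), len(tau_grid))``
    """
    alpha_grid = list(alpha_grid)
    tau_grid = list(tau_grid)
    if not alpha_grid or not tau_grid:
        raise ValueError("alpha and tau grids must be nonempty")
    if not len(y_roi_set):
        raise ValueError("need at least one ROI series set")
    surface = np.full((len(alpha_grid), len(tau_grid)), np.nan)
    for ia, a in enumerate(alpha_grid):
        for it, t in enumerate(tau_grid):
            errs = [cv_generalization_error(y_roi, design_set, L, a, t,
                                            memory_s=memory_s)
                    for y_roi in y_roi_set]
            surface[ia, it] = np.mean(errs)
    if np.all(np.isnan(surface)):
        raise ValueError("error surface is all-NaN")
    best = np.nanmin(surface)
    ties = np.argwhere(surface == best)
    # smaller tau wins, then smaller alpha
    ties = sorted(ties.tolist(), key=lambda ij: (tau_grid[ij[1]], alpha_grid[ij[0]]))
    ia, it = ties[0]
    return float(alpha_grid[ia]), float(tau_grid[it]), surface


def select_model_order(y_set, design_set, alpha: float, tau: float,
                       L_candidates=(1, 2, 3, 4, 5, 6),
                       memory_s: float = 24.0) -> int:
    """BIC-minimizing shared model order for both conditions.

    Ties favour the smaller order (the BIC penalty is monotone in the
    parameter count, so equal-RSS candidates already order this way).
    """
    L_candidates = list(L_candidates)
    if not L_candidates:
        raise ValueError("L_candidates must be nonempty")
    dt = design_set[0].tr_seconds
    M = int(round(memory_s / dt))
    best_L, best_bic = None, np.inf
    for L in sorted(L_candidates):
        basis = build_basis(L, M, alpha, tau, dt=dt)
        fit = _stacked_fit(y_set, design_set, basis, basis)
        if fit.bic < best_bic - 1e-12:
            best_L, best_bic = L, fit.bic
    return best_L


@dataclass(frozen=True)
class GroupHrfShape:
    """First principal component of a set of HRF curves."""

    curve: np.ndarray
    explained_variance: float


def group_hrf_shape(h_list) -> GroupHrfShape:
    """Group-level HRF shape as the first principal component.

    Computed from the uncentred curve stack (first right singular vector),
    sign-fixed so the largest-magnitude extremum is positive; the explained
    variance fraction is ``s1^2 / sum s^2``.
    """
    curves = [np.asarray(h, dtype=float) for h in h_list]
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    lengths = {len(c) for c in curves}
    if len(lengths) > 1:
        raise ValueError(f"curves have unequal lengths: {sorted(lengths)}")
    X = np.vstack(curves)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    pc1 = Vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    evr = float(s[0] ** 2 / np.sum(s**2))
    return GroupHrfShape(curve=pc1, explained_variance=evr)


# ---------------------------------------------------------------------------
# model / results interface


class HrfBasisModel:
    """Two-condition HRF basis-expansion model for one subject.

    Parameters
    ----------
    y_runs : sequence of 1-D arrays
        BOLD series, one per run (a single array is treated as one run).
    designs : sequence of TaskDesign
    basis_nov, basis_rep : BasisSet
        Per-condition bases; pass the same object for a shared basis.

    Examples
    --------
    >>> model = HrfBasisModel(y_runs, designs, basis, basis)
    >>> res = model.fit()
    >>> res.hrf("novelty").amplitude
    """

    def __init__(self, y_runs, designs, basis_nov: BasisSet,
                 basis_rep: BasisSet, sample_masks=None):
        if isinstance(designs, TaskDesign):
            designs = [designs]
            y_runs = [np.asarray(y_runs)]
        self.y_runs = [np.asarray(y, dtype=float) for y in y_runs]
        self.designs = list(designs)
        self.basis_nov = basis_nov
        self.basis_rep = basis_rep
        self.sample_masks = sample_masks

    @classmethod
    def from_grid_search(cls, y_runs, designs, y_roi_set=None, L: int = 2,
                         alpha_grid=DEFAULT_ALPHA_GRID,
                         tau_grid=DEFAULT_TAU_GRID, memory_s: float = 24.0):
        """Two-step construction: pick ``(alpha, tau)`` on ROI-average series
        (defaults to the target series itself), then build the model."""
        if y_roi_set is None:
            y_roi_set = [y_runs]
        a, t, _ = grid_search_basis(y_roi_set, designs, L, alpha_grid,
                                    tau_grid, memory_s)
        dt = designs[0].tr_seconds
        M = int(round(memory_s / dt))
        basis = build_basis(L, M, a, t, dt=dt)
        return cls(y_runs, designs, basis, basis)

    def fit(self) -> "HrfBasisResults":
        fit = _stacked_fit(self.y_runs, self.designs, self.basis_nov,
                           self.basis_rep, self.sample_masks)
        return HrfBasisResults(self, fit)


class HrfBasisResults:
    """Fitted HRF expansion: coefficients, HRFs and shape summaries."""

    def __init__(self, model: HrfBasisModel, fit: ExpansionFit):
        self.model = model
        self.expansion = fit
        self.params = fit.c
        self.mse = fit.mse
        self.bic = fit.bic

    def hrf(self, condition: str) -> HrfEstimate:
        basis = (self.model.basis_nov if condition == "novelty"
                 else self.model.basis_rep)
        return reconstruct_hrf(self.expansion, basis, condition)

    def summary(self) -> str:
        lines = ["HRF basis-expansion fit",
                 f"  runs: {len(self.model.y_runs)}   "
                 f"alpha={self.model.basis_nov.alpha:g}  "
                 f"tau={self.model.basis_nov.tau:g}  "
                 f"L={self.model.basis_nov.L}",
                 f"  in-sample mse: {self.mse:.5g}   BIC: {self.bic:.5g}"]
        for cond in ("novelty", "repetition"):
            est = self.hrf(cond)
            lines.append(
                f"  {cond:<12} amplitude={est.amplitude:+.4f}  "
                f"peak={est.peak_latency:.2f} s  fwhm={est.fwhm:.2f} s")
        return "\n".join(lines)
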