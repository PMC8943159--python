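"""Activation and gPPI connectivity GLMs with condition-specific HRFs.

Activation: the block series of each condition is convolved with its
*estimated* HRF, the resulting regressors are z-transformed per run and
entered into an OLS GLM with an intercept; refitting with the estimated
HRFs gives more accurate parameter estimates than reading amplitudes off
the HRF curves directly.  The primary contrast is novelty minus repetition
(NvR); run-level parameter estimates are averaged to one value per subject.

gPPI: condition-dependent coupling between a seed region (here typically the
locus coeruleus) and target voxels is modelled with
five regressors — one physiological (the demeaned seed mean series), two
psychological (block series convolved with the group-level seed HRF) and
their two products.  The connectivity contrast is the difference of the
two interaction parameter estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrf import convolve_to_length
from .simulate import TaskDesign

__all__ = [
    "ConditionGLM",
    "ConditionGLMResults",
    "GppiDesign",
    "GppiModel",
    "GppiResults",
    "fit_condition_glm",
    "build_gppi_design",
    "fit_gppi",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance regressor (condition never occurs?)")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("GLM design matrix is rank deficient")
    return beta


class ConditionGLM:
    """Activation GLM with condition-specific estimated HRFs.

    Parameters
    ----------
    y_runs : sequence of 1-D arrays (or a single array for one run)
    designs : sequence of TaskDesign
    h_nov, h_rep : ndarray
        Estimated HRFs sampled on the design TR grid.
    """

    def __init__(self, y_runs, designs, h_nov, h_rep, sample_masks=None):
        if isinstance(designs, TaskDesign):
            designs = [designs]
            y_runs = [np.asarray(y_runs)]
        self.y_runs = [np.asarray(y, dtype=float) for y in y_runs]
        self.designs = list(designs)
        self.h_nov = np.asarray(h_nov, dtype=float)
        self.h_rep = np.asarray(h_rep, dtype=float)
        self.sample_masks = sample_masks or [None] * len(self.designs)

    def _run_design(self, design: TaskDesign, mask=None) -> np.ndarray:
        n = design.n_volumes
        r_nov = convolve_to_length(design.x1, self.h_nov, n)
        r_rep = convolve_to_length(design.x2, self.h_rep, n)
        if mask is not None:
            r_nov, r_rep = r_nov[mask], r_rep[mask]
        r_nov, r_rep = _zscore(r_nov), _zscore(r_rep)
        return np.column_stack([np.ones(len(r_nov)), r_nov, r_rep])

    def fit(self) -> "ConditionGLMResults":
        pes = []
        for y, d, m in zip(self.y_runs, self.designs, self.sample_masks):
            X = self._run_design(d, m)
            if m is not None:
                y = y[m]
            beta = _ols(y, X)
            pes.append((beta[1], beta[2]))
        pes = np.asarray(pes)
        return ConditionGLMResults(self, pes)


@dataclass(frozen=True)
class ConditionGLMResults:
    """Per-run and run-averaged activation parameter estimates."""

    model: ConditionGLM
    run_pes: np.ndarray  # (n_runs, 2): novelty, repetition

    @property
    def pe_nov(self) -> float:
        return float(self.run_pes[:, 0].mean())

    @property
    def pe_rep(self) -> float:
        return float(self.run_pes[:, 1].mean())

    @property
    def contrast(self) -> float:
        """Novelty-versus-repetition (NvR) contrast estimate."""
        return self.pe_nov - self.pe_rep

    def summary(self) -> str:
        return ("Condition GLM (z-transformed HRF regressors)\n"
                f"  runs: {len(self.run_pes)}\n"
                f"  PE novelty:    {self.pe_nov:+.4f}\n"
                f"  PE repetition: {self.pe_rep:+.4f}\n"
                f"  NvR contrast:  {self.contrast:+.4f}")


def fit_condition_glm(y, design, h_nov, h_rep):
    """Functional wrapper: returns ``(pe_nov, pe_rep, contrast)``."""
    res = ConditionGLM(y, design, h_nov, h_rep).fit()
    return res.pe_nov, res.pe_rep, res.contrast


# ---------------------------------------------------------------------------
# gPPI


@dataclass(frozen=True)
class GppiDesign:
    """The five gPPI regressors for one run.

    ``physiological`` is the demeaned seed mean series; ``psych_*`` the
    block series convolved with the group-level seed HRF; ``inter_*`` the
    elementwise products of each psychological regressor with the
    physiological one.
    """

    physiological: np.ndarray
    psych_nov: np.ndarray
    psych_rep: np.ndarray
    inter_nov: np.ndarray
    inter_rep: np.ndarray

    def matrix(self, intercept: bool = True) -> np.ndarray:
        cols = [self.physiological, self.psych_nov, self.psych_rep,
                self.inter_nov, self.inter_rep]
        if intercept:
            cols = [np.ones(len(self.physiological))] + cols
        return np.column_stack(cols)


def build_gppi_design(seed_ts, design: TaskDesign, group_hrf,
                      zscore_psych: bool = False) -> GppiDesign:
    """Construct the 5-regressor gPPI design for one run.

    The seed series is demeaned before the products are formed, which keeps
    the interaction terms from aliasing the psychological main effects.  The
    products are taken at the BOLD level (no deconvolution of the seed to a
    neural-level series before multiplication), which differs from some gPPI
    variants that deconvolve first.  ``zscore_psych`` optionally standardizes
    the psychological regressors (off by default; standardization is part of
    the activation GLM only).
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if np.allclose(seed_ts, 0):
        raise ValueError("seed series is all-zero (empty seed mask?)")
    n = design.n_volumes
    if len(seed_ts) != n:
        raise ValueError("seed series length does not match the design")
    phys = seed_ts - seed_ts.mean()
    psych_nov = convolve_to_length(design.x1, np.asarray(group_hrf), n)
    psych_rep = convolve_to_length(design.x2, np.asarray(group_hrf), n)
    if zscore_psych:
        psych_nov = _zscore(psych_nov)
        psych_rep = _zscore(psych_rep)
    return GppiDesign(physiological=phys, psych_nov=psych_nov,
                      psych_rep=psych_rep, inter_nov=psych_nov * phys,
                      inter_rep=psych_rep * phys)


class GppiModel:
    """OLS fit of a target series on the 5 gPPI regressors plus intercept."""

    #: condition-number threshold above which a collinearity warning is issued
    CONDITION_WARN = 1e6

    def __init__(self, y_target, gppi_design: GppiDesign):
        self.y = np.asarray(y_target, dtype=float)
        self.design = gppi_design

    def fit(self) -> "GppiResults":
        import warnings

        X = self.design.matrix(intercept=True)
        cond = np.linalg.cond(X)
        if cond > self.CONDITION_WARN:
            warnings.warn(
                f"gPPI design is ill-conditioned (condition number {cond:.3g}); "
                "psychological and interaction regressors may be collinear",
                stacklevel=2)
        beta = _ols(self.y, X)
        return GppiResults(self, beta, cond)


class GppiResults:
    """Fitted gPPI parameter estimates and the connectivity contrast."""

    PARAM_NAMES = ("intercept", "physiological", "psych_nov", "psych_rep",
                   "inter_nov", "inter_rep")

    def __init__(self, model: GppiModel, params: np.ndarray, cond: float):
        self.model = model
        self.params = params
        self.condition_number = cond

    @property
    def pe_int_nov(self) -> float:
        return float(self.params[4])

    @property
    def pe_int_rep(self) -> float:
        return float(self.params[5])

    @property
    def fc_contrast(self) -> float:
        """NvR functional-connectivity contrast (interaction PE difference)."""
        return self.pe_int_nov - self.pe_int_rep

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.design.matrix(True) @ self.params

    def summary(self) -> str:
        rows = "\n".join(f"  {n:<14} {b:+.5f}"
                         for n, b in zip(self.PARAM_NAMES, self.params))
        return (f"gPPI GLM (condition number {self.condition_number:.3g})\n"
                f"{rows}\n  NvR FC contrast: {self.fc_contrast:+.5f}")


def fit_gppi(y_target, gppi_design: GppiDesign):
    """Functional wrapper: returns ``(pe_int_nov, pe_int_rep, fc_contrast)``."""
    res = GppiModel(y_target, gppi_design).fit()
    return res.pe_int_nov, res.pe_int_rep, res.fc_contrast


# ---------------------------------------------------------------------------
# voxel-wise maps (vectorized over voxels, averaged over runs)


def _contrast_map(run_data, run_designs, contrast_vec, sample_masks=None):
    maps = []
    masks = sample_masks or [None] * len(run_data)
    for data, X, m in zip(run_data, run_designs, masks):
        shape = data.shape[:-1]
        Y = data.reshape(-1, data.shape[-1]).T  # (t, voxels)
        if m is not None:
            Y = Y[m]
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("GLM design matrix is rank deficient")
        maps.append((contrast_vec @ beta).reshape(shape))
    return np.mean(maps, axis=0)


def activation_contrast_map(run_data, designs, h_nov, h_rep,
                            sample_masks=None) -> np.ndarray:
    """Run-averaged voxel-wise NvR activation contrast map.

    ``run_data`` is a sequence of 4-D arrays ``(x, y, z, t)``, one per run.
    Uses the same z-transformed HRF regressors as :class:`ConditionGLM`.
    """
    glm = ConditionGLM([np.zeros(d.n_volumes) for d in designs], designs,
                       h_nov, h_rep)
    masks = sample_masks or [None] * len(designs)
    Xs = [glm._run_design(d, m) for d, m in zip(designs, masks)]
    return _contrast_map(run_data, Xs, np.array([0.0, 1.0, -1.0]), masks)


def gppi_contrast_map(run_data, gppi_designs, sample_masks=None) -> np.ndarray:
    """Run-averaged voxel-wise gPPI NvR connectivity contrast map."""
    masks = sample_masks or [None] * len(run_data)
    Xs = []
    for g, m in zip(gppi_designs, masks):
        X = g.matrix(intercept=True)
        Xs.append(X if m is None else X[m])
    c = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
    return _contrast_map(run_data, Xs, c, masks)
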