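"""Group-level longitudinal statistics.

Cognitive composites (PACC5, memory, executive), paired amplitude tests,
the voxel-wise longitudinal interaction mixed model, cluster-extent FWER
correction by sign-flip permutation, BH-FDR, simple slopes, floodlight
(Johnson-Neyman) analysis and ICC reliability.

The core model relates an outcome measured over visits to an imaging
predictor (``PredA``, e.g. an NvR contrast estimate), amyloid burden
(``PredB``, PiB DVR) and time since baseline in years:

    y_ij = b0 + b1 Age_i + b2 Sex_i + b3 Edu_i + b4 PredA_i + b5 PredB_i
         + (b6 Age_i + b7 Sex_i + b8 Edu_i + b9 PredA_i + b10 PredB_i
            + b11 PredA_i PredB_i) Time_ij
         + b_0i + b_si Time_ij + e_ij

with Gaussian random intercepts and time-slopes per subject, fitted by
maximum likelihood.  Model (i) drops the amyloid moderation (PredA x Time
only); model (ii) is the full three-way interaction above.  Inference on
fixed effects uses Wald Z statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .simulate import PIB_CUTOFF

logger = logging.getLogger(__name__)

__all__ = [
    "PACC5_SUBTESTS",
    "MEMORY_SUBTESTS",
    "EXECUTIVE_SUBTESTS",
    "compute_composite",
    "compute_pacc5",
    "paired_amplitude_test",
    "LmeSpec",
    "LongitudinalInteractionModel",
    "LongitudinalInteractionResults",
    "FloodlightResult",
    "ClusterResult",
    "fit_voxelwise_lme",
    "gls_voxel_zmap",
    "cluster_lme_interaction",
    "cluster_extent_fwer",
    "fdr_adjust",
    "icc_reliability",
]

# subtest name -> direction (+1: higher is better; -1 flipped before z-averaging)
PACC5_SUBTESTS = {"dsst": 1, "fcsrt": 1, "logical_memory": 1, "mmse": 1,
                  "category_fluency": 1}
MEMORY_SUBTESTS = {"srt_delayed": 1, "fcsrt_free": 1, "logical_memory": 1}
EXECUTIVE_SUBTESTS = {"trails_b_minus_a": -1, "letter_number": 1,
                      "fas_fluency": 1}


def compute_composite(subtest_table: pd.DataFrame, subtests: dict,
                      baseline_reference: dict | None = None,
                      time_col: str = "time_years",
                      max_missing: int = 1) -> pd.Series:
    """Z-average cognitive composite with baseline-referenced z-scores.

    Each subtest is z-transformed using the mean and SD of the baseline
    (time 0) visits across subjects, sign-flipped where higher raw scores
    mean worse performance, and the composite is the mean of the available
    z-scores provided at most ``max_missing`` subtests are missing
    (otherwise the composite is missing).

    ``baseline_reference`` may supply ``{subtest: (mean, sd)}`` explicitly;
    by default it is computed from the rows with ``time_col == 0``.
    """
    if baseline_reference is None:
        base = subtest_table[np.isclose(subtest_table[time_col], 0.0)]
        baseline_reference = {}
        for name in subtests:
            m = base[name].mean()
            s = base[name].std(ddof=1)
            baseline_reference[name] = (m, s)
    z = pd.DataFrame(index=subtest_table.index)
    for name, direction in subtests.items():
        m, s = baseline_reference[name]
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"baseline SD for subtest {name!r} is zero")
        z[name] = direction * (subtest_table[name] - m) / s
    n_present = z.notna().sum(axis=1)
    composite = z.mean(axis=1, skipna=True)
    composite[n_present < len(subtests) - max_missing] = np.nan
    return composite


def compute_pacc5(subtest_table: pd.DataFrame,
                  baseline_reference: dict | None = None,
                  time_col: str = "time_years") -> pd.Series:
    """PACC5 composite: mean of 5 baseline-referenced z-scores (DSST, FCSRT
    free+total, Logical Memory delayed, MMSE, category fluency); at most one
    missing subtest is allowed."""
    return compute_composite(subtest_table, PACC5_SUBTESTS,
                             baseline_reference, time_col, max_missing=1)


def paired_amplitude_test(amp_nov, amp_rep):
    """Two-tailed paired t-test on run-averaged HRF amplitudes.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(amp_nov, dtype=float)
    b = np.asarray(amp_rep, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(a - b) == 0:
        raise ValueError("zero-variance paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# the longitudinal interaction mixed model


@dataclass(frozen=True)
class LmeSpec:
    """Specification of the longitudinal mixed model.

    ``model`` "i" fits PredA x Time (no amyloid moderation); "ii" adds PiB
    and the three-way PredA x PiB x Time interaction.  Covariates enter as
    main effects and, when ``covariate_time_interactions``, also crossed
    with time; those crossings can be pruned at p > 0.10 when removing them
    changes the remaining estimates by < 10 %.  ``pib_mode`` selects the
    continuous DVR or its dichotomization at the 1.324 cut-off.
    """

    model: str = "ii"
    covariates: tuple = ("age", "sex", "edu")
    covariate_time_interactions: bool = True
    prune_covariate_interactions: bool = True
    prune_p: float = 0.10
    prune_max_change: float = 0.10
    random_slope: bool = True
    pib_mode: str = "continuous"

    def __post_init__(self):
        if self.model not in ("i", "ii"):
            raise ValueError(f"model must be 'i' or 'ii', got {self.model!r}")
        if self.pib_mode not in ("continuous", "dichotomous"):
            raise ValueError(f"unknown pib_mode {self.pib_mode!r}")


class LongitudinalInteractionModel:
    """Voxel/ROI-level longitudinal interaction model (statsmodels MixedLM).

    Build with :meth:`from_dataframe` on a long-format cohort table, then
    :meth:`fit`.  Column names default to the cohort CSV convention
    (``outcome``, ``pred``, ``pib_dvr``, ``time_years``, ``subject``).
    """

    def __init__(self, data: pd.DataFrame, spec: LmeSpec = LmeSpec(),
                 outcome: str = "outcome", pred: str = "pred",
                 pib: str = "pib_dvr", time: str = "time_years",
                 subject: str = "subject"):
        self.spec = spec
        self.outcome = outcome
        self.pred = pred
        self.time = time
        self.subject = subject
        data = data.copy()
        if spec.model == "ii" and spec.pib_mode == "dichotomous":
            data["_pib"] = (data[pib] > PIB_CUTOFF).astype(float)
        elif spec.model == "ii":
            data["_pib"] = data[pib].astype(float)
        self.pib = "_pib" if spec.model == "ii" else None
        self.data = data

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, spec: LmeSpec = LmeSpec(),
                       **names) -> "LongitudinalInteractionModel":
        return cls(cohort, spec, **names)

    # -- formula assembly ---------------------------------------------------

    def _terms(self, covariate_time: bool = True) -> list[str]:
        s = self.spec
        t, p = self.time, self.pred
        terms = list(s.covariates) + [p, t, f"{p}:{t}"]
        if s.model == "ii":
            b = self.pib
            terms += [b, f"{b}:{t}", f"{p}:{b}:{t}"]
        if covariate_time and s.covariate_time_interactions:
            terms += [f"{c}:{t}" for c in s.covariates]
        return terms

    def formula(self, covariate_time: bool = True) -> str:
        return f"{self.outcome} ~ " + " + ".join(self._terms(covariate_time))

    # -- fitting ------------------------------------------------------------

    def _fit_formula(self, formula: str, random_slope: bool, start=None):
        re_formula = f"~{self.time}" if random_slope else "~1"
        model = smf.mixedlm(formula, self.data, groups=self.data[self.subject],
                            re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(reml=False, method="lbfgs", start_params=start)
        return res

    def _fit_with_fallback(self, formula: str):
        """ML fit; falls back to intercept-only random effects when the
        slope variance collapses to the boundary or the fit fails."""
        res, used_slope = None, self.spec.random_slope
        if self.spec.random_slope:
            try:
                res = self._fit_formula(formula, random_slope=True)
                slope_var = float(res.cov_re.iloc[1, 1])
                if not res.converged or slope_var < 1e-8 * max(res.scale, 1e-12):
                    res = None
            except (np.linalg.LinAlgError, ValueError):
                res = None
            if res is None:
                used_slope = False
        if res is None:
            res = self._fit_formula(formula, random_slope=False)
        return res, used_slope

    def fit(self) -> "LongitudinalInteractionResults":
        s = self.spec
        res, used_slope = self._fit_with_fallback(self.formula())
        pruned = []
        if s.covariate_time_interactions and s.prune_covariate_interactions:
            cand = [f"{c}:{self.time}" for c in s.covariates]
            weak = [c for c in cand
                    if c in res.pvalues.index and res.pvalues[c] > s.prune_p]
            if weak:
                keep = [t for t in self._terms() if t not in weak]
                res2, used2 = self._fit_with_fallback(
                    f"{self.outcome} ~ " + " + ".join(keep))
                common = [n for n in res2.fe_params.index
                          if n in res.fe_params.index and n != "Intercept"]
                old = res.fe_params[common]
                new = res2.fe_params[common]
                denom = np.maximum(np.abs(old), 1e-12)
                if float(np.max(np.abs(new - old) / denom)) < s.prune_max_change:
                    res, used_slope, pruned = res2, used2, weak
        return LongitudinalInteractionResults(self, res, used_slope, pruned)


class LongitudinalInteractionResults:
    """Fixed-effect estimates, Wald inference and moderation analyses."""

    def __init__(self, model: LongitudinalInteractionModel, smres,
                 random_slope_used: bool, pruned_terms: list):
        self.model = model
        self._smres = smres
        self.random_slope_used = random_slope_used
        self.pruned_terms = pruned_terms
        self.params = smres.fe_params
        k = len(self.params)
        cov = np.asarray(smres.cov_params())[:k, :k]
        self.cov_params = pd.DataFrame(cov, index=self.params.index,
                                       columns=self.params.index)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)
        self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)
        self.converged = bool(smres.converged)

    # -- helpers ------------------------------------------------------------

    def _slope_gradient(self, values: dict) -> pd.Series:
        """Gradient of the outcome-vs-time slope w.r.t. the fixed effects.

        A parameter named ``a:b:time`` contributes ``value(a)*value(b)`` to
        the slope; variables absent from ``values`` count as 0.
        """
        t = self.model.time
        grad = pd.Series(0.0, index=self.params.index)
        for name in self.params.index:
            parts = name.split(":")
            if t not in parts:
                continue
            others = [p for p in parts if p != t]
            w = 1.0
            for p in others:
                w *= values.get(p, 0.0)
            grad[name] = w
        return grad

    def time_slope(self, values: dict):
        """Outcome-vs-time slope and its SE at the given variable values."""
        g = self._slope_gradient(values)
        est = float(g @ self.params)
        se = float(np.sqrt(g @ self.cov_params.to_numpy() @ g))
        return est, se

    def simple_slopes(self, moderator: str | None = None, levels=None,
                      at: dict | None = None) -> pd.DataFrame:
        """Marginal time-slopes at moderator levels (mean and +/- 1 SD).

        Other variables interacting with time are held at the values in
        ``at`` (default 0).  Returns a table with estimate, SE, Wald Z and p
        per level.
        """
        moderator = moderator or self.model.pred
        names = {p for name in self.params.index for p in name.split(":")}
        if moderator not in names:
            raise ValueError(f"moderator {moderator!r} is not in the model")
        if levels is None:
            col = self.model.data[moderator]
            m, s = float(col.mean()), float(col.std(ddof=1))
            levels = {"mean-1sd": m - s, "mean": m, "mean+1sd": m + s}
        elif not isinstance(levels, dict):
            levels = {f"{v:g}": float(v) for v in levels}
        rows = []
        for label, v in levels.items():
            vals = dict(at or {})
            vals[moderator] = v
            est, se = self.time_slope(vals)
            z = est / se if se > 0 else np.nan
            rows.append({"level": label, "moderator_value": v, "slope": est,
                         "se": se, "z": z, "p": 2 * stats.norm.sf(abs(z))})
        return pd.DataFrame(rows).set_index("level")

    # -- floodlight ---------------------------------------------------------

    def _interaction_effect(self, value: float):
        """Effect of the imaging predictor on the time-slope at moderator
        value ``value`` (three-way model) or unconditionally (two-way)."""
        p, t, b = self.model.pred, self.model.time, self.model.pib
        g = pd.Series(0.0, index=self.params.index)

        def term(*parts):
            for name in self.params.index:
                if set(name.split(":")) == set(parts):
                    return name
            return None

        t2 = term(p, t)
        if t2 is None:
            raise ValueError("model has no predictor-by-time interaction")
        g[t2] = 1.0
        if b is not None:
            t3 = term(p, b, t)
            if t3 is not None:
                g[t3] = value
        est = float(g @ self.params)
        se = float(np.sqrt(g @ self.cov_params.to_numpy() @ g))
        return est, se

    def floodlight(self, grid=None, alpha: float = 0.05,
                   fdr: bool = True) -> "FloodlightResult":
        """Region of moderator (PiB) values where the predictor-by-time
        association is significant, with BH-FDR across grid points."""
        if self.model.pib is None:
            raise ValueError("floodlight requires the three-way model ('ii')")
        if grid is None:
            col = self.model.data[self.model.pib]
            grid = np.linspace(float(col.min()), float(col.max()), 41)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("moderator grid is empty")
        est = np.empty(grid.size)
        se = np.empty(grid.size)
        for i, v in enumerate(grid):
            est[i], se[i] = self._interaction_effect(v)
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        sig = fdr_adjust(p, alpha) if fdr else p < alpha
        region = grid[sig]
        return FloodlightResult(
            grid=grid, slope=est, se=se, z=z, p=p, significant=sig,
            region_min=float(region.min()) if region.size else np.nan,
            region_max=float(region.max()) if region.size else np.nan)

    def jn_boundary(self, z_crit: float = 1.959963984540054) -> np.ndarray:
        """Analytic Johnson-Neyman boundaries: moderator values where the
        Wald statistic of the conditional predictor-by-time effect equals
        ``z_crit`` (roots of a quadratic; may be 0, 1 or 2 real values)."""
        p, t, b = self.model.pred, self.model.time, self.model.pib
        if b is None:
            raise ValueError("JN boundary requires the three-way model")
        n2 = [n for n in self.params.index
              if set(n.split(":")) == {p, t}][0]
        n3 = [n for n in self.params.index
              if set(n.split(":")) == {p, b, t}][0]
        b2, b3 = self.params[n2], self.params[n3]
        v22 = self.cov_params.loc[n2, n2]
        v33 = self.cov_params.loc[n3, n3]
        v23 = self.cov_params.loc[n2, n3]
        zz = z_crit**2
        # (b2 + b3 m)^2 = zz (v22 + 2 v23 m + v33 m^2)
        a = b3**2 - zz * v33
        bb = 2 * (b2 * b3 - zz * v23)
        c = b2**2 - zz * v22
        disc = bb**2 - 4 * a * c
        if a == 0:
            return np.array([-c / bb]) if bb != 0 else np.array([])
        if disc < 0:
            return np.array([])
        r = np.sqrt(disc)
        return np.sort(np.array([(-bb - r) / (2 * a), (-bb + r) / (2 * a)]))

    def summary(self) -> str:
        head = (f"Longitudinal interaction model ({self.model.spec.model}), "
                f"ML, random {'intercept+slope' if self.random_slope_used else 'intercept only'}\n"
                f"  observations: {len(self.model.data)}   "
                f"subjects: {self.model.data[self.model.subject].nunique()}\n")
        if self.pruned_terms:
            head += f"  pruned covariate-by-time terms: {self.pruned_terms}\n"
        tab = pd.DataFrame({"estimate": self.params, "se": self.bse,
                            "z": self.zvalues, "p": self.pvalues})
        return head + tab.to_string(float_format=lambda v: f"{v:.4f}")


@dataclass(frozen=True)
class FloodlightResult:
    """Per-grid-point simple-slope tests and the significant region."""

    grid: np.ndarray
    slope: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    region_min: float
    region_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"moderator": self.grid, "slope": self.slope,
                             "se": self.se, "z": self.z, "p": self.p,
                             "significant": self.significant})


# ---------------------------------------------------------------------------
# voxel-wise mapping


def fit_voxelwise_lme(contrast_values, cohort: pd.DataFrame,
                      spec: LmeSpec = LmeSpec(), subject_order=None,
                      terms: tuple | None = None, **names) -> pd.DataFrame:
    """Fit the longitudinal model per voxel.

    Parameters
    ----------
    contrast_values : ndarray ``(n_subjects, n_voxels)``
        One imaging predictor value per subject per voxel.
    cohort : DataFrame
        Long-format table; its ``pred`` column is replaced voxel by voxel.
    subject_order : sequence, optional
        Subject ids corresponding to the rows of ``contrast_values``
        (defaults to the sorted unique subjects of the cohort).
    terms : tuple of str, optional
        Fixed-effect terms to report (defaults to all).

    Returns
    -------
    DataFrame indexed by voxel with MultiIndex columns ``(term, stat)`` for
    stats ``estimate``, ``se``, ``z``.  Voxels whose fit fails even after
    the random-intercept fallback are left as NaN.
    """
    contrast_values = np.atleast_2d(np.asarray(contrast_values, dtype=float))
    subjects = (np.asarray(subject_order) if subject_order is not None
                else np.sort(cohort["subject"].unique()))
    if contrast_values.shape[0] != len(subjects):
        raise ValueError("contrast rows do not match the subject count")
    pred_col = names.get("pred", "pred")
    base = cohort.copy()
    sub_idx = base["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    records = {}
    for v in range(contrast_values.shape[1]):
        base[pred_col] = contrast_values[sub_idx, v]
        model = LongitudinalInteractionModel.from_dataframe(base, spec, **names)
        try:
            res = model.fit()
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("voxel %d: mixed-model fit failed; flagged missing", v)
            records[v] = {}
            continue
        rec = {}
        for t in (terms or res.params.index):
            if t in res.params.index:
                rec[(t, "estimate")] = res.params[t]
                rec[(t, "se")] = res.bse[t]
                rec[(t, "z")] = res.zvalues[t]
        records[v] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


# ---------------------------------------------------------------------------
# fast GLS route for voxel-wise interaction maps
#
# Refitting the full ML mixed model per voxel inside a permutation loop is
# prohibitively slow, so cluster inference on interaction maps uses a
# plug-in GLS approximation: variance components are estimated once (from
# the model with the voxel-averaged predictor), every subject block is
# whitened with the implied marginal covariance, and per-voxel Wald Z
# statistics come from whitened OLS.  Only the predictor-dependent columns
# change across voxels, so the whitened design is assembled incrementally.


class _GlsVoxelEngine:
    def __init__(self, cohort: pd.DataFrame, spec: LmeSpec, mean_pred,
                 subject_order, **names):
        base = cohort.copy()
        pred_col = names.get("pred", "pred")
        sub_col = names.get("subject", "subject")
        self.subjects = (np.asarray(subject_order) if subject_order is not None
                         else np.sort(base[sub_col].unique()))
        sub_map = {s: i for i, s in enumerate(self.subjects)}
        base["_subidx"] = base[sub_col].map(sub_map)
        base = base.sort_values(["_subidx", names.get("time", "time_years")],
                                kind="stable").reset_index(drop=True)
        base[pred_col] = np.asarray(mean_pred)[base["_subidx"].to_numpy()]
        self.model = LongitudinalInteractionModel.from_dataframe(
            base, spec, **names)
        res = self.model.fit()
        sm = res._smres
        cov_re = np.atleast_2d(np.asarray(sm.cov_re))
        scale = float(sm.scale)
        data = self.model.data
        t = data[self.model.time].to_numpy(dtype=float)
        self.sub_idx = data["_subidx"].to_numpy()

        # fixed (pred-independent) columns, in self-describing order
        cols, self.col_names = [np.ones(len(data))], ["Intercept"]
        for c in spec.covariates:
            cols.append(data[c].to_numpy(dtype=float))
            self.col_names.append(c)
        cols.append(t)
        self.col_names.append("time")
        if spec.model == "ii":
            pib = data[self.model.pib].to_numpy(dtype=float)
            cols += [pib, pib * t]
            self.col_names += ["pib", "pib:time"]
        else:
            pib = None
        if spec.covariate_time_interactions:
            for c in spec.covariates:
                cols.append(data[c].to_numpy(dtype=float) * t)
                self.col_names.append(f"{c}:time")
        base_X = np.column_stack(cols)

        # pred-dependent row patterns: pred, pred:time [, pred:pib:time]
        pat = [np.ones(len(data)), t]
        self.pred_names = ["pred", "pred:time"]
        if spec.model == "ii":
            pat.append(pib * t)
            self.pred_names.append("pred:pib:time")
        pattern = np.column_stack(pat)

        y = data[self.model.outcome].to_numpy(dtype=float)
        self.Xw_base = np.empty_like(base_X)
        self.pattern_w = np.empty_like(pattern)
        self.yw = np.empty_like(y)
        for i in range(len(self.subjects)):
            rows = np.flatnonzero(self.sub_idx == i)
            ti = t[rows]
            Z = np.column_stack([np.ones(len(rows)), ti])[:, :cov_re.shape[0]]
            Vi = Z @ cov_re @ Z.T + scale * np.eye(len(rows))
            Wi = np.linalg.inv(np.linalg.cholesky(Vi))
            self.Xw_base[rows] = Wi @ base_X[rows]
            self.pattern_w[rows] = Wi @ pattern[rows]
            self.yw[rows] = Wi @ y[rows]
        self.term_index = len(self.col_names) + self.pred_names.index(
            "pred:pib:time" if spec.model == "ii" else "pred:time")

    def zmap(self, pred_matrix: np.ndarray, yw=None) -> np.ndarray:
        """Wald Z of the highest-order interaction per voxel.

        ``pred_matrix`` has one row per subject, one column per voxel;
        ``yw`` optionally replaces the whitened outcome (used by the
        Freedman-Lane permutation scheme).
        """
        yw = self.yw if yw is None else yw
        pred_rows = pred_matrix[self.sub_idx]  # (n_obs, V)
        nv = pred_matrix.shape[1]
        z = np.empty(nv)
        k = self.term_index
        for v in range(nv):
            X = np.hstack([self.Xw_base,
                           self.pattern_w * pred_rows[:, v:v + 1]])
            beta, _, _, _ = np.linalg.lstsq(X, yw, rcond=None)
            xtx_inv = np.linalg.inv(X.T @ X)
            z[v] = beta[k] / np.sqrt(xtx_inv[k, k])
        return z

    def freedman_lane_outcomes(self, rng, n_permutations):
        """Whitened outcomes with reduced-model residuals permuted across
        subjects (Freedman-Lane): the predictor-free model is fitted once,
        its residuals are re-assigned subject-wise, and the fit is added
        back.  Requires identical visit schedules across subjects."""
        counts = np.bincount(self.sub_idx)
        if len(set(counts)) != 1:
            raise ValueError("Freedman-Lane block permutation needs "
                             "identical visit schedules across subjects")
        gamma, _, _, _ = np.linalg.lstsq(self.Xw_base, self.yw, rcond=None)
        fitted = self.Xw_base @ gamma
        resid = (self.yw - fitted).reshape(len(counts), counts[0])
        for _ in range(n_permutations):
            perm = rng.permutation(len(counts))
            yield fitted + resid[perm].reshape(-1)


def gls_voxel_zmap(contrast_values, cohort, spec: LmeSpec = LmeSpec(),
                   subject_order=None, **names) -> np.ndarray:
    """Per-voxel Wald Z map of the highest-order interaction via plug-in GLS.

    Variance components are estimated once from the voxel-averaged
    predictor model; see the module notes.  ``contrast_values`` is
    ``(n_subjects, n_voxels)``.
    """
    cv = np.atleast_2d(np.asarray(contrast_values, dtype=float))
    eng = _GlsVoxelEngine(cohort, spec, cv.mean(axis=1), subject_order, **names)
    return eng.zmap(cv)


def cluster_lme_interaction(subject_pred_maps, cohort,
                            spec: LmeSpec = LmeSpec(), cdt_z: float = 3.1,
                            alpha: float = 0.05, n_permutations: int = 500,
                            seed: int = 0, mask=None, subject_order=None,
                            **names) -> ClusterResult:
    """Cluster-extent FWER inference on the voxel-wise interaction Z map.

    The observed map is the plug-in GLS Wald Z of the highest-order
    interaction; the max-cluster-size null uses Freedman-Lane permutation —
    residuals of the predictor-free reduced model are re-assigned across
    subjects and the reduced-model fit added back — which breaks any
    predictor-outcome association while preserving both the covariate
    structure of the outcome and the spatial covariance of the maps.
    """
    maps = np.asarray(subject_pred_maps, dtype=float)
    n = maps.shape[0]
    shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat = maps.reshape(n, -1)[:, mask.reshape(-1)]
    eng = _GlsVoxelEngine(cohort, spec, flat.mean(axis=1), subject_order,
                          **names)

    def full_map(zvals):
        out = np.zeros(shape)
        out[mask] = zvals
        return out

    z_map = full_map(eng.zmap(flat))
    supra = (np.abs(z_map) > cdt_z) & mask
    labels, nlab = ndimage.label(supra, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones(shape), labels,
                               np.arange(1, nlab + 1)).astype(int)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=int)
    for p, yw_star in enumerate(
            eng.freedman_lane_outcomes(rng, n_permutations)):
        zp_map = full_map(eng.zmap(flat, yw=yw_star))
        lab_p, nl = ndimage.label((np.abs(zp_map) > cdt_z) & mask,
                                  structure=_CONN26)
        null_max[p] = 0 if nl == 0 else int(np.max(ndimage.sum_labels(
            np.ones(shape), lab_p, np.arange(1, nl + 1))))
    pvals = np.array([(1 + np.sum(null_max >= s)) / (n_permutations + 1)
                      for s in sizes])
    peaks, coords = [], []
    absz = np.abs(z_map)
    for k in range(1, nlab + 1):
        in_k = labels == k
        idx = np.unravel_index(np.argmax(np.where(in_k, absz, -np.inf)), shape)
        peaks.append(z_map[idx])
        coords.append(tuple(int(i) for i in idx))
    return ClusterResult(labels=labels, sizes=sizes, peak_z=np.asarray(peaks),
                         peak_coords=coords, pvalues=pvals, z_map=z_map,
                         null_max_sizes=null_max)


# ---------------------------------------------------------------------------
# multiple-comparison control


@dataclass(frozen=True)
class ClusterResult:
    """Supra-threshold clusters with permutation FWER p-values."""

    labels: np.ndarray
    sizes: np.ndarray
    peak_z: np.ndarray
    peak_coords: list
    pvalues: np.ndarray
    z_map: np.ndarray
    null_max_sizes: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean mask of voxels in clusters with FWER p < alpha."""
        keep = np.flatnonzero(self.pvalues < alpha) + 1
        return np.isin(self.labels, keep)


def _one_sample_z(maps2d: np.ndarray) -> np.ndarray:
    """Z-converted one-sample t statistics, subjects along axis 0."""
    n = maps2d.shape[0]
    mean = maps2d.mean(axis=0)
    sd = maps2d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    # t -> Z through matched tail probabilities, sign preserved
    return np.sign(t) * stats.norm.isf(
        np.clip(stats.t.sf(np.abs(t), n - 1), 1e-300, 1.0))


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _max_cluster_size(zflat: np.ndarray, shape, cdt: float, mask_flat) -> int:
    supra = np.zeros(len(zflat), dtype=bool)
    supra[mask_flat] = np.abs(zflat[mask_flat]) > cdt
    lab, nlab = ndimage.label(supra.reshape(shape), structure=_CONN26)
    if nlab == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones(shape), lab,
                                         np.arange(1, nlab + 1))))


def cluster_extent_fwer(subject_maps: np.ndarray, cdt_z: float = 3.1,
                        alpha: float = 0.05, n_permutations: int = 1000,
                        seed: int = 0, mask=None) -> ClusterResult:
    """Cluster-extent FWER correction by sign-flip permutation.

    Clusters are formed at ``|Z| > cdt_z`` (two-tailed; presets 4.5 / 3.1 /
    2.3) with 26-connectivity from the Z-converted one-sample t map across
    ``subject_maps`` (shape ``(n_subjects, x, y, z)``).  The null
    distribution of the maximum cluster size is built by randomly flipping
    subject signs; cluster FWER p-values are
    ``(1 + #{null max >= size}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives imprecise FWER "
                      "p-values", stacklevel=2)
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask_flat = mask.reshape(-1)
    flat = maps.reshape(n, -1)

    z = _one_sample_z(flat)
    z_map = np.where(mask_flat, z, 0.0).reshape(shape)
    supra = np.abs(z_map) > cdt_z
    supra &= mask
    labels, nlab = ndimage.label(supra, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones(shape), labels,
                               np.arange(1, nlab + 1)).astype(int)

    rng = np.random.default_rng(seed)
    msq = np.mean(flat**2, axis=0)  # invariant under sign flips
    null_max = np.empty(n_permutations, dtype=int)
    for p in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        mean = (signs @ flat) / n
        var = (msq - mean**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        zp = np.sign(t) * stats.norm.isf(
            np.clip(stats.t.sf(np.abs(t), n - 1), 1e-300, 1.0))
        null_max[p] = _max_cluster_size(zp, shape, cdt_z, mask_flat)

    pvals = np.array([(1 + np.sum(null_max >= s)) / (n_permutations + 1)
                      for s in sizes])
    peaks, coords = [], []
    absz = np.abs(z_map)
    for k in range(1, nlab + 1):
        in_k = labels == k
        idx = np.unravel_index(np.argmax(np.where(in_k, absz, -np.inf)), shape)
        peaks.append(z_map[idx])
        coords.append(tuple(int(i) for i in idx))
    return ClusterResult(labels=labels, sizes=sizes,
                         peak_z=np.asarray(peaks), peak_coords=coords,
                         pvalues=pvals, z_map=z_map, null_max_sizes=null_max)


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    NaN p-values are excluded from the procedure (count logged) and never
    rejected.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("fdr_adjust: excluded %d NaN p-values", n_bad)
    if ok.sum():
        rej, _, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        out[ok] = rej
    return out


# ---------------------------------------------------------------------------
# reliability


def icc_reliability(long_scores: pd.DataFrame, subject: str = "subject",
                    score: str = "score") -> float:
    """Two-way mixed-effects consistency ICC, single measure (ICC(3,1)).

    Visits are ranked within subject in order of appearance; subjects with
    fewer than 2 visits are excluded (count logged), and all included
    subjects are truncated to the common visit count so the two-way ANOVA
    decomposition is balanced.
    """
    df = long_scores[[subject, score]].dropna().copy()
    counts = df.groupby(subject).size()
    excluded = counts[counts < 2]
    if len(excluded):
        logger.info("icc_reliability: excluded %d single-visit subjects",
                    len(excluded))
    keep = counts[counts >= 2]
    if keep.empty:
        raise ValueError("no subject has >= 2 visits")
    k = int(keep.min())
    df = df[df[subject].isin(keep.index)]
    df["visit"] = df.groupby(subject).cumcount()
    df = df[df["visit"] < k]
    wide = df.pivot(index=subject, columns="visit", values=score).to_numpy()
    n = wide.shape[0]
    grand = wide.mean()
    row_means = wide.mean(axis=1)
    col_means = wide.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((wide - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))
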