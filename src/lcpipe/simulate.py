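"""Synthetic inputs with known ground truth for the whole pipeline.

Everything downstream (HRF estimation, activation GLM, gPPI, longitudinal
mixed-effects mapping) is exercised on data generated here: block task
designs matching the face-name encoding paradigm, region-specific ground
truth HRFs, noisy 4D BOLD runs with confound structure, and longitudinal
cohorts with planted interaction effects.  Every generator is a pure
function of its seed.

The default task layout reproduces the encoding paradigm: a 5-s fixation
block at start and end of each run, two novelty and two repetition blocks of
7 trials (4.75 s each, padded with jittered fixation to 40 s per block),
interleaved with 25-s fixation blocks, six runs.  The scheduled run length
is 5 + 40 + 25 + 40 + 25 + 40 + 25 + 40 + 5 = 245 s (4 min 5 s); with
TR = 2 s and the default 127 volumes the trailing fixation is padded by 9 s
so the printed volume count and the printed run duration are both honoured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisSet

__all__ = [
    "TaskDesign",
    "BlockSpec",
    "NoiseSpec",
    "GroundTruth",
    "AmyloidMixture",
    "make_task_design",
    "make_ground_truth_hrf",
    "default_roi_masks",
    "simulate_bold_run",
    "simulate_cohort",
    "PIB_CUTOFF",
]

#: Amyloid (PiB DVR) positivity cut-off for partial-volume-corrected data,
#: derived from Gaussian mixture modelling on the full cohort upstream of
#: this package; taken as a constant here.
PIB_CUTOFF = 1.324

NOVELTY = "novelty"
REPETITION = "repetition"
FIXATION = "fixation"


@dataclass(frozen=True)
class TaskDesign:
    """Per-run two-condition block design sampled on the TR grid.

    ``x1`` (novelty) and ``x2`` (repetition) are 0/1 indicator series of
    length ``n_volumes``; they are never simultaneously positive.  ``events``
    lists ``(condition, onset_s, duration_s)`` for every trial and fixation
    block.
    """

    tr_seconds: float
    n_volumes: int
    x1: np.ndarray
    x2: np.ndarray
    events: tuple
    run_index: int = 0

    def __post_init__(self):
        if len(self.x1) != self.n_volumes or len(self.x2) != self.n_volumes:
            raise ValueError("indicator series must have length n_volumes")
        if np.any((self.x1 > 0) & (self.x2 > 0)):
            raise ValueError("novelty and repetition cannot overlap")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_seconds

    def block_intervals(self, condition: str, max_gap_s: float = 5.0):
        """(onset, duration) intervals of trials merged into blocks.

        Trials separated by sub-``max_gap_s`` jitter gaps belong to the same
        block; longer gaps (inter-block fixation) split blocks.
        """
        out = []
        for lab, onset, dur in sorted(self.events, key=lambda e: e[1]):
            if lab != condition:
                continue
            if out and onset - (out[-1][0] + out[-1][1]) < max_gap_s:
                out[-1] = (out[-1][0], onset + dur - out[-1][0])
            else:
                out.append((onset, dur))
        return out


@dataclass(frozen=True)
class BlockSpec:
    """Layout of one run.  Defaults give the 245-s encoding paradigm."""

    initial_fixation_s: float = 5.0
    final_fixation_s: float = 5.0
    inter_fixation_s: float = 25.0
    block_s: float = 40.0
    trial_s: float = 4.75
    trials_per_block: int = 7
    block_order: tuple = (NOVELTY, REPETITION, NOVELTY, REPETITION)

    @property
    def scheduled_duration_s(self) -> float:
        n = len(self.block_order)
        inter = self.inter_fixation_s * max(n - 1, 0)
        return (self.initial_fixation_s + self.final_fixation_s
                + self.block_s * n + inter)


def _block_events(spec: BlockSpec, condition: str, onset: float,
                  rng: np.random.Generator | None):
    """Trials within one task block; jitter pads the block to ``block_s``."""
    pad_total = spec.block_s - spec.trial_s * spec.trials_per_block
    if pad_total < -1e-9:
        raise ValueError("trials do not fit inside the block duration")
    k = spec.trials_per_block
    if rng is None:
        pads = np.full(k, pad_total / k)
    else:
        w = rng.dirichlet(np.ones(k))
        pads = w * pad_total
    events, t = [], onset
    for i in range(k):
        events.append((condition, round(t, 6), spec.trial_s))
        t += spec.trial_s + pads[i]
    return events


def make_task_design(tr_seconds: float = 2.0, n_runs: int = 6,
                     block_spec: BlockSpec | None = None,
                     n_volumes: int = 127,
                     seed: int | None = None) -> list[TaskDesign]:
    """Generate per-run block designs.

    Parameters
    ----------
    tr_seconds : float
        Repetition time of the TR sampling grid.
    n_runs : int
        Number of functional runs (6 in the reference paradigm).
    block_spec : BlockSpec, optional
        Run layout; defaults to the 245-s paradigm.
    n_volumes : int
        Volumes per run (127 by default); trailing fixation absorbs the
        difference between ``n_volumes * tr_seconds`` and the scheduled
        duration.
    seed : int, optional
        Seeds the within-block fixation jitter; ``None`` spreads the padding
        evenly (deterministic layout).

    Raises
    ------
    ValueError
        If the scheduled layout overflows ``n_volumes * tr_seconds``.
    """
    spec = block_spec or BlockSpec()
    run_s = n_volumes * tr_seconds
    overflow = spec.scheduled_duration_s - run_s
    if overflow > 1e-9:
        raise ValueError(
            f"block layout ({spec.scheduled_duration_s:g} s) overflows the run "
            f"({run_s:g} s) by {overflow:g} s")
    rng = None if seed is None else np.random.default_rng(seed)
    designs = []
    for r in range(n_runs):
        events = [(FIXATION, 0.0, spec.initial_fixation_s)]
        t = spec.initial_fixation_s
        for i, cond in enumerate(spec.block_order):
            events.extend(_block_events(spec, cond, t, rng))
            t += spec.block_s
            if i < len(spec.block_order) - 1:
                events.append((FIXATION, t, spec.inter_fixation_s))
                t += spec.inter_fixation_s
        # trailing fixation padded to fill the full volume count
        events.append((FIXATION, t, run_s - t))
        x1 = _indicator(spec, NOVELTY, events, tr_seconds, n_volumes)
        x2 = _indicator(spec, REPETITION, events, tr_seconds, n_volumes)
        designs.append(TaskDesign(tr_seconds=tr_seconds, n_volumes=n_volumes,
                                  x1=x1, x2=x2, events=tuple(events),
                                  run_index=r))
    return designs


def _indicator(spec, condition, events, tr, n_volumes):
    """Block-level 0/1 series: onsets snapped to the nearest TR sample."""
    x = np.zeros(n_volumes)
    # mark whole blocks (contiguous trial spans) rather than single trials:
    # the paradigm is a block design and the jittered gaps stay "on task"
    starts, ends = [], []
    for lab, onset, dur in events:
        if lab != condition:
            continue
        if starts and onset < ends[-1] + spec.trial_s + 1e-6:
            ends[-1] = max(ends[-1], onset + dur)
        else:
            starts.append(onset)
            ends.append(onset + dur)
    for s, e in zip(starts, ends):
        # extend each block span to its scheduled length (trailing jitter pad)
        e = max(e, s + spec.block_s) if spec.trials_per_block > 1 else e
        i0 = int(round(s / tr))
        i1 = int(round(e / tr))
        x[i0:min(i1, n_volumes)] = 1.0
    return x


# ---------------------------------------------------------------------------
# ground-truth HRFs


def make_ground_truth_hrf(shape: str = "double-gamma",
                          params: dict | None = None,
                          dt: float = 2.0) -> np.ndarray:
    """Sampled ground-truth HRF of finite memory, zero at lag 0.

    Parameters
    ----------
    shape : {"double-gamma", "laguerre", "gamma-delay"}
        ``double-gamma``: canonical positive lobe peaking near 5 s with an
        undershoot; ``laguerre``: an exact linear combination ``B @ coef`` of
        a supplied :class:`~lcpipe.basis.BasisSet`; ``gamma-delay``: single
        gamma density with a pure onset delay.
    params : dict, optional
        ``amplitude`` (peak value, default 1), ``duration_s`` (support,
        default 24), plus per-shape parameters: double-gamma ``peak1``/
        ``peak2`` (gamma shapes, default 6/16), ``undershoot_ratio`` (1/6),
        ``latency_shift_s`` (0); gamma-delay ``shape`` (6), ``scale`` (0.9),
        ``delay_s`` (1); laguerre ``basis`` (BasisSet) and ``coef``.
    dt : float
        Sample spacing in seconds.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    p = dict(params or {})
    if shape == "laguerre":
        basis: BasisSet = p["basis"]
        coef = np.asarray(p["coef"], dtype=float)
        return basis.B @ coef
    duration = float(p.get("duration_s", 24.0))
    t = np.arange(0.0, duration + dt / 2, dt)
    amplitude = float(p.get("amplitude", 1.0))
    if shape == "double-gamma":
        a1 = float(p.get("peak1", 6.0))
        a2 = float(p.get("peak2", 16.0))
        ratio = float(p.get("undershoot_ratio", 1.0 / 6.0))
        shift = float(p.get("latency_shift_s", 0.0))
        if a1 <= 0 or a2 <= 0:
            raise ValueError("gamma shape parameters must be positive")
        ts = np.clip(t - shift, 0.0, None)
        h = stats.gamma.pdf(ts, a1) - ratio * stats.gamma.pdf(ts, a2)
    elif shape == "gamma-delay":
        k = float(p.get("shape", 6.0))
        theta = float(p.get("scale", 0.9))
        delay = float(p.get("delay_s", 1.0))
        if k <= 0 or theta <= 0:
            raise ValueError("gamma shape/scale must be positive")
        h = stats.gamma.pdf(np.clip(t - delay, 0.0, None), k, scale=theta)
    else:
        raise ValueError(f"unknown HRF shape {shape!r}")
    h[0] = 0.0
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h * (amplitude / peak)
    return h


# ---------------------------------------------------------------------------
# BOLD simulation


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for one voxel time-series.

    ``white_sd`` is the innovation SD of an AR(1) process with coefficient
    ``ar1`` (set ``ar1 = 0`` for white noise); ``drift_slope`` is a linear
    drift in signal units per second; ``physio_amps``/``physio_freqs_hz``
    define pseudo-physiological sinusoids with random per-voxel phase.
    """

    white_sd: float = 0.5
    ar1: float = 0.3
    drift_slope: float = 0.002
    physio_amps: tuple = (0.1,)
    physio_freqs_hz: tuple = (0.03,)

    def __post_init__(self):
        if self.white_sd < 0 or any(a < 0 for a in self.physio_amps):
            raise ValueError("noise SDs/amplitudes must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError(f"AR(1) coefficient must lie in (-1, 1), got {self.ar1}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to generate one subject's BOLD runs.

    ``beta_nov``/``beta_rep`` give activation amplitudes per voxel (scalars
    broadcast over the active mask), ``coupling_nov``/``coupling_rep`` the
    condition-specific seed-to-target gPPI coupling strengths.
    """

    hrf_nov: np.ndarray
    hrf_rep: np.ndarray
    beta_nov: float = 1.0
    beta_rep: float = 0.5
    coupling_nov: float = 0.0
    coupling_rep: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0


def default_roi_masks(grid_shape=(12, 12, 8)) -> dict:
    """Disjoint labelled ROI masks on a small voxel grid.

    Provides a seed region (the connectivity seed), a gPPI target region, an
    active region for plain activation, a 4th-ventricle-like region adjacent
    to the seed, lateral ventricles and white matter (nuisance ROIs).
    """
    nx, ny, nz = grid_shape
    if nx < 10 or ny < 10 or nz < 7:
        raise ValueError("grid must be at least 10 x 10 x 7 voxels")

    def box(x0, x1, y0, y1, z0, z1):
        m = np.zeros(grid_shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    masks = {
        "seed": box(1, 3, 1, 3, 1, 3),
        "ventricle_4th": box(1, 3, 3, 5, 1, 3),
        "target": box(nx - 4, nx - 1, 1, 4, 1, 4),
        "active": box(nx - 4, nx - 1, ny - 4, ny - 1, 1, 4),
        "lateral_ventricles": box(1, 3, ny - 3, ny - 1, nz - 3, nz - 1),
        "white_matter": box(nx // 2 - 1, nx // 2 + 1, ny // 2 - 1, ny // 2 + 1,
                            nz - 3, nz - 1),
    }
    pairs = list(masks)
    for i, a in enumerate(pairs):
        for b in pairs[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"masks {a!r} and {b!r} overlap")
    return masks


def _ar1_noise(rng, spec: NoiseSpec, n, size):
    w = rng.normal(0.0, spec.white_sd, size=(n,) + size)
    if spec.ar1 == 0.0 or spec.white_sd == 0.0:
        return w
    e = np.empty_like(w)
    e[0] = w[0] / np.sqrt(1.0 - spec.ar1**2)  # stationary start
    for t in range(1, n):
        e[t] = spec.ar1 * e[t - 1] + w[t]
    return e


def simulate_bold_run(design: TaskDesign, ground_truth: GroundTruth,
                      grid_shape=(12, 12, 8), seed: int = 0,
                      masks: dict | None = None):
    """Simulate one noisy 4D BOLD run plus its confound table.

    The voxel signal is the two-condition convolution model used generatively:
    ``beta_nov * (x1 * h_nov) + beta_rep * (x2 * h_rep)`` inside the active
    and seed masks, plus — inside the target mask — condition-scaled copies
    of the (demeaned, noisy) seed mean series for gPPI ground truth, plus
    AR(1) noise, linear drift and sinusoidal pseudo-physiology everywhere.

    Returns
    -------
    data : ndarray, shape ``grid_shape + (n_volumes,)``
    confounds : DataFrame
        Six synthetic motion series and the three nuisance ROI mean series.
    masks : dict of bool ndarrays
    """
    masks = default_roi_masks(grid_shape) if masks is None else masks
    if np.any(masks["seed"] & masks["target"]):
        raise ValueError("seed and target masks overlap")
    rng = np.random.default_rng(seed)
    gt = ground_truth
    n = design.n_volumes
    t = design.frame_times

    conv_nov = np.convolve(design.x1, gt.hrf_nov)[:n]
    conv_rep = np.convolve(design.x2, gt.hrf_rep)[:n]
    task = gt.beta_nov * conv_nov + gt.beta_rep * conv_rep

    data = np.zeros(grid_shape + (n,))
    active = masks["seed"] | masks["active"]
    data[active] += task

    noise = _ar1_noise(rng, gt.noise, n, grid_shape)  # (n, x, y, z)
    noise = np.moveaxis(noise, 0, -1)
    drift = gt.noise.drift_slope * t
    physio = np.zeros(grid_shape + (n,))
    for amp, f in zip(gt.noise.physio_amps, gt.noise.physio_freqs_hz):
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=grid_shape)
        physio += amp * np.sin(2 * np.pi * f * t + phase[..., None])
    data += noise + drift + physio

    # gPPI ground truth: target voxels receive condition-gated copies of the
    # observed seed mean series (couplings act at BOLD level, as analysed)
    if gt.coupling_nov != 0.0 or gt.coupling_rep != 0.0:
        seed_ts = data[masks["seed"]].mean(axis=0)
        seed_ts = seed_ts - seed_ts.mean()
        hn = gt.hrf_nov / max(np.max(np.abs(gt.hrf_nov)), 1e-12)
        hr = gt.hrf_rep / max(np.max(np.abs(gt.hrf_rep)), 1e-12)
        gate_nov = np.convolve(design.x1, hn)[:n]
        gate_rep = np.convolve(design.x2, hr)[:n]
        data[masks["target"]] += (gt.coupling_nov * gate_nov * seed_ts
                                  + gt.coupling_rep * gate_rep * seed_ts)

    motion = np.cumsum(rng.normal(0, 0.01, size=(n, 6)), axis=0)
    confounds = pd.DataFrame(
        motion, columns=[f"motion_{i}" for i in range(1, 7)])
    for name, key in (("roi_ventricle_4th", "ventricle_4th"),
                      ("roi_lateral_ventricles", "lateral_ventricles"),
                      ("roi_white_matter", "white_matter")):
        confounds[name] = data[masks[key]].mean(axis=0)
    return data, confounds, masks


# ---------------------------------------------------------------------------
# longitudinal cohort


@dataclass(frozen=True)
class AmyloidMixture:
    """Two-component amyloid (PiB DVR) mixture split at the 1.324 cut-off.

    Components are normal distributions truncated below (negative group) or
    above (positive group) the cut-off, so mixture membership and dichotomous
    classification coincide exactly.  Defaults follow the reported group
    medians/IQRs (negative ~1.18, positive ~1.84 DVR) and the 36/128
    positive share.
    """

    weight_positive: float = 36.0 / 128.0
    mean_negative: float = 1.18
    sd_negative: float = 0.05
    mean_positive: float = 1.84
    sd_positive: float = 0.45
    cutoff: float = PIB_CUTOFF

    def __post_init__(self):
        if not 0 <= self.weight_positive <= 1:
            raise ValueError("weight_positive must lie in [0, 1]")
        if self.sd_negative <= 0 or self.sd_positive <= 0:
            raise ValueError("component SDs must be positive")

    def sample(self, n: int, rng: np.random.Generator, stratify: bool = True):
        """Draw ``n`` DVR values; ``stratify`` fixes the positive count to
        ``round(n * weight_positive)`` (otherwise Bernoulli membership)."""
        if stratify:
            n_pos = int(round(n * self.weight_positive))
            pos = np.zeros(n, dtype=bool)
            pos[rng.permutation(n)[:n_pos]] = True
        else:
            pos = rng.random(n) < self.weight_positive
        dvr = np.empty(n)
        a_neg = -np.inf, (self.cutoff - self.mean_negative) / self.sd_negative
        a_pos = (self.cutoff - self.mean_positive) / self.sd_positive, np.inf
        n_neg = int((~pos).sum())
        if n_neg:
            dvr[~pos] = stats.truncnorm.rvs(
                a_neg[0], a_neg[1], loc=self.mean_negative,
                scale=self.sd_negative, size=n_neg, random_state=rng)
        if pos.sum():
            dvr[pos] = stats.truncnorm.rvs(
                a_pos[0], a_pos[1], loc=self.mean_positive,
                scale=self.sd_positive, size=int(pos.sum()), random_state=rng)
        return dvr, pos


def default_eq9_betas() -> dict:
    """Neutral fixed-effect vector (all zero); planted effects are set per
    study.  Keys: b0..b11 in the order intercept, age, sex, edu, predA,
    predB, age:time, sex:time, edu:time, predA:time, predB:time,
    predA:predB:time."""
    return {f"b{i}": 0.0 for i in range(12)}


def simulate_cohort(n_subjects: int = 128,
                    eq9_betas: dict | None = None,
                    random_effect_sds=(0.8, 0.08, 0.0, 0.35),
                    amyloid_mixture: AmyloidMixture | None = None,
                    visit_schedule=None,
                    seed: int = 0,
                    stratify_amyloid: bool = True,
                    pred_sd: float = 1.0) -> pd.DataFrame:
    """Simulate a longitudinal cohort from the interaction mixed model.

    The outcome for subject *i* at visit *j* is

    ``y_ij = b0 + b1 Age_i + b2 Sex_i + b3 Edu_i + b4 PredA_i + b5 PredB_i
    + (b6 Age_i + b7 Sex_i + b8 Edu_i + b9 PredA_i + b10 PredB_i
    + b11 PredA_i PredB_i) * Time_ij + b_si Time_ij + b_0i + e_ij``

    with Gaussian random intercepts/slopes (SDs ``tau0``, ``taus``,
    correlation ``rho``) and residual SD ``sigma``;
    ``random_effect_sds = (tau0, taus, rho, sigma)``.  ``PredB`` is the
    amyloid DVR drawn from ``amyloid_mixture``; a dichotomous
    ``amyloid_positive`` flag uses the 1.324 cut-off.  ``PredA`` is the
    imaging predictor (standard normal scaled by ``pred_sd``).

    ``visit_schedule`` maps to per-subject visit times in years: ``None``
    gives five annual visits (0..4) for everyone; a sequence of arrays gives
    explicit per-subject schedules (dropout = shorter arrays); every subject
    keeps a baseline visit at time 0.
    """
    tau0, taus, rho, sigma = random_effect_sds
    if tau0 < 0 or taus < 0 or sigma < 0:
        raise ValueError("variance components must be nonnegative")
    if not -1 <= rho <= 1:
        raise ValueError("random-effect correlation must lie in [-1, 1]")
    betas = dict(default_eq9_betas(), **(eq9_betas or {}))
    mixture = amyloid_mixture or AmyloidMixture()
    rng = np.random.default_rng(seed)

    age = rng.normal(70.07, 8.86, n_subjects)
    sex = (rng.random(n_subjects) < 0.55).astype(int)
    edu = rng.integers(12, 21, n_subjects).astype(float)
    pred_a = rng.normal(0.0, pred_sd, n_subjects)
    dvr, positive = mixture.sample(n_subjects, rng, stratify=stratify_amyloid)

    cov = np.array([[tau0**2, rho * tau0 * taus],
                    [rho * tau0 * taus, taus**2]])
    re = rng.multivariate_normal([0.0, 0.0], cov, size=n_subjects)

    if visit_schedule is None:
        visit_schedule = [np.arange(5.0)] * n_subjects
    rows = []
    for i in range(n_subjects):
        times = np.asarray(visit_schedule[i], dtype=float)
        if times.size == 0 or abs(times.min()) > 1e-12:
            raise ValueError(f"subject {i} lacks a baseline visit at time 0")
        slope = (betas["b6"] * age[i] + betas["b7"] * sex[i]
                 + betas["b8"] * edu[i] + betas["b9"] * pred_a[i]
                 + betas["b10"] * dvr[i]
                 + betas["b11"] * pred_a[i] * dvr[i] + re[i, 1])
        level = (betas["b0"] + betas["b1"] * age[i] + betas["b2"] * sex[i]
                 + betas["b3"] * edu[i] + betas["b4"] * pred_a[i]
                 + betas["b5"] * dvr[i] + re[i, 0])
        eps = rng.normal(0.0, sigma, times.size) if sigma > 0 else np.zeros(times.size)
        for j, tt in enumerate(times):
            rows.append({"subject": i, "time_years": tt,
                         "outcome": level + slope * tt + eps[j],
                         "age": age[i], "sex": sex[i], "edu": edu[i],
                         "pib_dvr": dvr[i],
                         "amyloid_positive": bool(dvr[i] > mixture.cutoff),
                         "pred": pred_a[i]})
    return pd.DataFrame(rows)
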