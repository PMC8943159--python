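"""File formats and configuration.

Images are NIfTI-1 (via nibabel), events and confounds are BIDS-style TSV,
the cohort is a long-format CSV, configuration is YAML and reports are JSON.
All voxel coordinates in tables are 0-based; times are seconds and visit
times years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import TaskDesign, FIXATION, NOVELTY, REPETITION

__all__ = [
    "load_bold",
    "save_bold",
    "load_events",
    "save_events",
    "design_from_events",
    "PipelineConfig",
]

KNOWN_LABELS = {NOVELTY, REPETITION, FIXATION}


def load_bold(path):
    """Read a 4D BOLD NIfTI.

    Returns ``(data, tr_seconds, affine)``; the TR comes from the 4th pixdim
    of the header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got {data.ndim}D: {path}")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"no TR recorded in the header of {path}")
    return data, tr, img.affine


def save_bold(data, path, tr_seconds: float, affine=None) -> None:
    """Write a 3D/4D array as NIfTI-1, recording the TR for 4D data."""
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if np.asarray(data).ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_seconds
        img.header.set_zooms(zooms)
    img.to_filename(str(path))


def save_events(design: TaskDesign, path) -> None:
    """Write the event table as BIDS-style TSV (onset, duration, trial_type)."""
    df = pd.DataFrame(
        [{"onset": o, "duration": d, "trial_type": lab}
         for lab, o, d in design.events])
    df.to_csv(path, sep="\t", index=False)


def load_events(path) -> list[tuple]:
    """Read an events TSV into ``(label, onset, duration)`` tuples.

    Unknown trial types, negative onsets and overlapping novelty/repetition
    events are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"onset", "duration", "trial_type"}
    if not need <= set(df.columns):
        raise ValueError(f"events file lacks columns {sorted(need - set(df.columns))}")
    events = []
    for _, row in df.iterrows():
        lab = str(row["trial_type"])
        if lab not in KNOWN_LABELS:
            raise ValueError(f"unknown trial type {lab!r}")
        onset, dur = float(row["onset"]), float(row["duration"])
        if onset < 0:
            raise ValueError(f"negative onset {onset}")
        events.append((lab, onset, dur))
    task = sorted((o, o + d, lab) for lab, o, d in events if lab != FIXATION)
    for (s1, e1, l1), (s2, e2, l2) in zip(task, task[1:]):
        if s2 < e1 - 1e-9 and l1 != l2:
            raise ValueError("novelty and repetition events overlap")
    return events


def design_from_events(events, tr_seconds: float, n_volumes: int,
                       run_index: int = 0) -> TaskDesign:
    """Rebuild a TaskDesign from an event list.

    Contiguous same-condition events separated by sub-TR jitter gaps are
    merged into blocks, a block's end extends to the next event's onset when
    the remaining gap is sub-TR (the trailing jitter pad), and block
    onsets/offsets snap to the nearest TR sample.
    """
    all_onsets = np.sort([o for _, o, _ in events])

    def indicator(condition):
        x = np.zeros(n_volumes)
        spans = []
        for lab, onset, dur in sorted(events, key=lambda e: e[1]):
            if lab != condition:
                continue
            if spans and onset - spans[-1][1] < tr_seconds:
                spans[-1][1] = onset + dur
            else:
                spans.append([onset, onset + dur])
        for s, e in spans:
            nxt = all_onsets[all_onsets >= e - 1e-9]
            if nxt.size and nxt[0] - e < tr_seconds:
                e = nxt[0]
            x[int(round(s / tr_seconds)):
              min(int(round(e / tr_seconds)), n_volumes)] = 1.0
        return x

    return TaskDesign(tr_seconds=tr_seconds, n_volumes=n_volumes,
                      x1=indicator(NOVELTY), x2=indicator(REPETITION),
                      events=tuple(events), run_index=run_index)


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs.

    With ``simulate=True`` the inputs are generated into ``output_dir``;
    otherwise the ``*_paths`` must point at existing files.
    """

    output_dir: str = "lcpipe_out"
    simulate: bool = True
    seed: int = 0
    # simulation scale
    n_subjects: int = 4
    n_runs: int = 6
    n_volumes: int = 127
    tr_seconds: float = 2.0
    grid_shape: tuple = (12, 12, 8)
    # basis / HRF estimation
    order_L: int = 2
    memory_s: float = 24.0
    alpha_grid: tuple = tuple(0.25 * k for k in range(1, 13))
    tau_grid: tuple = tuple(0.5 * k for k in range(0, 9))
    # preprocessing
    smooth_fwhm_mm: tuple = (3.0, 3.0, 6.0)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    # group statistics
    cohort_size: int = 128
    cdt_z: float = 3.1
    cluster_alpha: float = 0.05
    n_permutations: int = 500
    fdr_q: float = 0.05
    eq9_betas: dict = field(default_factory=dict)
    # pre-existing inputs (used when simulate=False)
    bold_paths: tuple = ()
    events_paths: tuple = ()
    cohort_path: str | None = None
    run_group_stage: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        def native(v):
            if isinstance(v, (tuple, list)):
                return [native(x) for x in v]
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, np.integer):
                return int(v)
            return v

        d = {k: native(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def validate(self) -> None:
        if self.n_volumes <= 0 or self.tr_seconds <= 0:
            raise ValueError("n_volumes and tr_seconds must be positive")
        if self.order_L < 1:
            raise ValueError("order_L must be >= 1")
        if not self.alpha_grid or not self.tau_grid:
            raise ValueError("alpha/tau grids must be nonempty")
        if not 0 < self.cluster_alpha < 1 or not 0 < self.fdr_q < 1:
            raise ValueError("alpha and q must lie in (0, 1)")
        if not self.simulate:
            missing = [p for p in (*self.bold_paths, *self.events_paths)
                       if not Path(p).exists()]
            if self.run_group_stage:
                if self.cohort_path is None:
                    raise ValueError("group stage enabled but no cohort path")
                if not Path(self.cohort_path).exists():
                    missing.append(self.cohort_path)
            if missing:
                raise ValueError(f"missing input files: {missing}")
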