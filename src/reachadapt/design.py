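"""Experiment designs: trial schedules and visual-stimulus properties.

Three visuomotor-rotation experiments share a common session structure:
a 20-trial baseline phase with veridical feedback, a 180-trial adaptation
phase in which the cursor is rotated counter-clockwise of the hand by an
angle drawn independently per trial from a Gaussian (mean 12 deg, SD 4 deg),
and a 100-trial no-feedback washout phase.  During adaptation, cursor
feedback is flashed briefly at reach midpoint (and, depending on the
experiment, at endpoint) at one of four blur levels:

* ``L``   -- a single veridical cursor dot (lowest uncertainty),
* ``M``   -- a 50-point cloud with per-axis SD 0.5 cm,
* ``H``   -- a 50-point cloud with per-axis SD 1.0 cm,
* ``INF`` -- no feedback at all (unlimited uncertainty).

Experiment 1 delivers feedback at midpoint only; Experiment 2 delivers
matched levels at midpoint and endpoint; Experiment 3 crosses midpoint and
endpoint levels over {L, H} x {L, H}.  Each adaptation condition occurs on
exactly 45 trials, interleaved pseudo-randomly.  Schedules are trial-matched
across participants: one seed fully determines the design.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UncertaintyLevel",
    "TrialSpec",
    "TrialSchedule",
    "StimulusCloud",
    "BASELINE_TRIALS",
    "ADAPTATION_TRIALS",
    "WASHOUT_TRIALS",
    "ROTATION_MEAN_DEG",
    "ROTATION_SD_DEG",
    "sample_perturbations",
    "build_schedule",
    "generate_cloud",
    "angular_subtense",
    "schedule_to_frame",
    "schedule_from_frame",
    "write_schedule",
    "read_schedule",
]

# Session structure (trial counts per phase) and the rotation distribution.
BASELINE_TRIALS = 20
ADAPTATION_TRIALS = 180
WASHOUT_TRIALS = 100
ROTATION_MEAN_DEG = 12.0
ROTATION_SD_DEG = 4.0

# Cloud geometry: number of dots and per-axis SD (cm) per level.
CLOUD_N_POINTS = 50
CLOUD_SD_CM = {"M": 0.5, "H": 1.0}

TRIALS_PER_CONDITION = 45  # 180 adaptation trials / 4 conditions


class UncertaintyLevel(enum.IntEnum):
    """Ordinal visual-uncertainty level of a feedback event.

    The integer values give the ordinal position L < M < H < INF and are
    used directly to index the 4-vectors of uncertainty-scaling parameters.
    """

    L = 0
    M = 1
    H = 2
    INF = 3

    @property
    def label(self) -> str:
        return self.name


def _coerce_level(level) -> UncertaintyLevel:
    if isinstance(level, UncertaintyLevel):
        return level
    if isinstance(level, str):
        try:
            return UncertaintyLevel[level.upper()]
        except KeyError:
            raise ValueError(f"unknown uncertainty level: {level!r}") from None
    return UncertaintyLevel(level)


@dataclass(frozen=True)
class TrialSpec:
    """One trial of a session.

    ``rotation_deg`` is the imposed visuomotor rotation (counter-clockwise
    positive), zero outside the adaptation phase.  ``mp_uncertainty`` /
    ``ep_uncertainty`` are ``None`` on trials without a midpoint/endpoint
    feedback event by design (baseline's continuous veridical feedback is
    not a discrete event; washout has no feedback at all), which is distinct
    from the adaptation-phase no-feedback condition ``INF``.
    """

    index: int  # 1-based trial number
    phase: str  # {"baseline", "adaptation", "washout"}
    rotation_deg: float
    mp_uncertainty: Optional[UncertaintyLevel] = None
    ep_uncertainty: Optional[UncertaintyLevel] = None

    def __post_init__(self):
        if self.phase not in ("baseline", "adaptation", "washout"):
            raise ValueError(f"unknown phase: {self.phase!r}")
        if self.phase != "adaptation" and self.rotation_deg != 0.0:
            raise ValueError("rotation must be 0 outside the adaptation phase")


@dataclass(frozen=True)
class TrialSchedule:
    """The full per-trial design of one experiment, for one seed."""

    experiment_id: int
    trials: tuple
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def rotations(self) -> np.ndarray:
        return np.array([t.rotation_deg for t in self.trials])

    def phase_slice(self, phase: str) -> list:
        return [t for t in self.trials if t.phase == phase]


@dataclass(frozen=True)
class StimulusCloud:
    """Dot offsets (cm) of one feedback stimulus relative to the cursor."""

    points: np.ndarray  # (n_points, 2) offsets in cm
    sd_cm: float
    level: UncertaintyLevel

    @property
    def n_points(self) -> int:
        return len(self.points)


def sample_perturbations(
    n_trials: int, mean_deg: float = ROTATION_MEAN_DEG,
    sd_deg: float = ROTATION_SD_DEG, seed: int = 0,
) -> np.ndarray:
    """Draw i.i.d. Gaussian rotation magnitudes, one per trial.

    The same seed yields the same sequence, which is how schedules are
    trial-matched across synthetic participants.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.normal(mean_deg, sd_deg, size=n_trials)


def _condition_labels(experiment_id: int) -> list:
    """(mp, ep) level pairs, one per adaptation condition."""
    if experiment_id == 1:
        return [(lvl, None) for lvl in UncertaintyLevel]
    if experiment_id == 2:
        return [(lvl, lvl) for lvl in UncertaintyLevel]
    if experiment_id == 3:
        lo, hi = UncertaintyLevel.L, UncertaintyLevel.H
        return [(lo, lo), (lo, hi), (hi, lo), (hi, hi)]
    raise ValueError(f"unknown experiment_id: {experiment_id!r}")


def build_schedule(experiment_id: int, seed: int = 0) -> TrialSchedule:
    """Generate the 300-trial schedule of one experiment.

    The adaptation-phase condition sequence is a seeded permutation of a
    balanced label vector (45 copies of each of the four conditions), and
    the rotation of each adaptation trial is an independent Gaussian draw.
    Baseline and washout trials carry no rotation and no discrete feedback
    event.
    """
    conditions = _condition_labels(experiment_id)
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), TRIALS_PER_CONDITION)
    order = rng.permutation(labels)
    rotations = rng.normal(ROTATION_MEAN_DEG, ROTATION_SD_DEG,
                           size=ADAPTATION_TRIALS)

    trials = []
    idx = 1
    for _ in range(BASELINE_TRIALS):
        trials.append(TrialSpec(idx, "baseline", 0.0))
        idx += 1
    for k in range(ADAPTATION_TRIALS):
        mp, ep = conditions[order[k]]
        trials.append(TrialSpec(idx, "adaptation", float(rotations[k]), mp, ep))
        idx += 1
    for _ in range(WASHOUT_TRIALS):
        trials.append(TrialSpec(idx, "washout", 0.0))
        idx += 1
    return TrialSchedule(experiment_id, tuple(trials), seed)


def generate_cloud(level, seed: int = 0) -> StimulusCloud:
    """Sample the dot offsets of one feedback stimulus.

    ``L`` is a single dot centred on the cursor, ``M``/``H`` are 50-dot
    2-D Gaussian clouds (SD 0.5 / 1.0 cm per axis), ``INF`` is empty.
    """
    level = _coerce_level(level)
    if level is UncertaintyLevel.L:
        pts = np.zeros((1, 2))
        sd = 0.0
    elif level is UncertaintyLevel.INF:
        pts = np.zeros((0, 2))
        sd = 0.0
    else:
        sd = CLOUD_SD_CM[level.label]
        rng = np.random.default_rng(seed)
        pts = rng.normal(0.0, sd, size=(CLOUD_N_POINTS, 2))
    return StimulusCloud(pts, sd, level)


def angular_subtense(sd_cm: float, radius_cm: float) -> float:
    """Arc-angle (degrees) subtended by ``sd_cm`` at distance ``radius_cm``.

    Uses the arc convention deg = (s / r) * 180 / pi, which reproduces the
    printed stimulus geometry: a 0.5 cm extent spans 5.73 deg at the 5 cm
    midpoint and 2.86 deg at the 10 cm endpoint.
    """
    if radius_cm <= 0:
        raise ValueError("radius_cm must be > 0")
    return math.degrees(sd_cm / radius_cm)


# ---------------------------------------------------------------------------
# Serialization: one row per trial, missing uncertainty as an empty field.

_SCHEDULE_COLUMNS = ["trial", "phase", "rotation_deg",
                     "mp_uncertainty", "ep_uncertainty"]


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    rows = [
        {
            "trial": t.index,
            "phase": t.phase,
            "rotation_deg": t.rotation_deg,
            "mp_uncertainty": t.mp_uncertainty.label if t.mp_uncertainty is not None else "",
            "ep_uncertainty": t.ep_uncertainty.label if t.ep_uncertainty is not None else "",
        }
        for t in schedule
    ]
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def schedule_from_frame(frame: pd.DataFrame, experiment_id: int = 0,
                        seed: int = -1) -> TrialSchedule:
    trials = []
    for _, row in frame.iterrows():
        mp = row["mp_uncertainty"]
        ep = row["ep_uncertainty"]
        mp = _coerce_level(mp) if isinstance(mp, str) and mp else (
            None if not isinstance(mp, (int, np.integer)) else _coerce_level(mp))
        ep = _coerce_level(ep) if isinstance(ep, str) and ep else (
            None if not isinstance(ep, (int, np.integer)) else _coerce_level(ep))
        trials.append(TrialSpec(int(row["trial"]), str(row["phase"]),
                                float(row["rotation_deg"]), mp, ep))
    return TrialSchedule(experiment_id, tuple(trials), seed)


def write_schedule(schedule: TrialSchedule, path) -> None:
    # %.17g round-trips float64 exactly
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False,
                                       float_format="%.17g")


def read_schedule(path, experiment_id: int = 0, seed: int = -1) -> TrialSchedule:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        float_precision="round_trip")
    return schedule_from_frame(frame, experiment_id, seed)
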