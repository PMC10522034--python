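"""Synthetic participants: forward-simulated behavioural datasets.

The generator runs a chosen generative model over an experiment schedule
and records the three behavioural series the analyses consume — initial
movement vector (the executed reach direction at onset), midpoint hand
angle and endpoint hand angle.  Motor execution noise is injected into the
plan *before* the midpoint error is computed, so the feedback controller
and the learning rules react to the executed (noisy) movement exactly as
they would in a closed-loop participant; observation noise is added to the
recorded angles afterwards.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import TrialSchedule, build_schedule, schedule_to_frame
from .models import (ModelParams, ModelSpec, predict_session,
                     schedule_arrays)

__all__ = [
    "NoiseModel",
    "BehaviouralDataset",
    "generate_participant",
    "generate_cohort",
    "cohort_group_average",
    "DEFAULT_GENERATOR_SPEC",
    "default_generator_params",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Trial-level noise: execution noise on y(t0), measurement noise on
    the recorded angles (degrees, i.i.d. Gaussian)."""

    motor_sd: float = 1.0
    observation_sd: float = 0.0

    def __post_init__(self):
        if self.motor_sd < 0 or self.observation_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class BehaviouralDataset:
    """Observed or simulated per-trial behaviour aligned to a schedule."""

    schedule: TrialSchedule
    imv: np.ndarray
    mp_angle: np.ndarray
    ep_angle: np.ndarray
    participant_id: str = "p0"
    provenance: dict = field(default_factory=lambda: {"kind": "observed"})

    def __post_init__(self):
        n = len(self.schedule)
        for name in ("imv", "mp_angle", "ep_angle"):
            series = np.asarray(getattr(self, name), dtype=float)
            if series.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, series)

    def to_frame(self) -> pd.DataFrame:
        frame = schedule_to_frame(self.schedule)
        frame["imv"] = self.imv
        frame["mp_angle"] = self.mp_angle
        frame["ep_angle"] = self.ep_angle
        return frame


# The default generative model: the two-state state-aim-scaling model (the
# best-supported class) with mid-range parameter values and a scaling
# vector that decreases with uncertainty.
DEFAULT_GENERATOR_SPEC = ModelSpec("state_aim_scaling", n_states=2)

# Shared mid-range defaults: a slow stable adaptive state, a moderate
# feedback controller whose correction strength decreases with blur, and a
# feedforward scaling vector that decreases over L, M, H with the
# no-feedback level behaving like a middling condition.  Rates and
# retentions are chosen so the closed trial-to-trial loop is contractive
# and simulated hand angles stay in a behaviourally plausible range
# (tens of degrees) over a 300-trial session.
_COMMON = dict(alpha_s=0.01, beta_s=0.93, alpha_fb=0.01, beta_fb=0.8,
               x_fb_init=0.3, nu_fb=(0.8, 0.5, 0.3, 0.0), gamma=0.6)


def default_generator_params(family: str = "state_aim_scaling") -> ModelParams:
    """Mid-range two-state generator parameters per scaling family.

    These are the fixed study conditions of the synthetic experiments, not
    fitted quantities: each family gets a clearly graded uncertainty
    scaling vector at the locus it modulates.
    """
    if family == "error_scaling":
        return ModelParams(alpha_f=0.25, beta_f=0.7, lambda_f=1.0,
                           nu_ff=(1.0, 0.6, 0.3, 0.0), **_COMMON)
    if family == "retention_scaling":
        return ModelParams(alpha_f=0.08, beta_f=0.9, lambda_f=1.0,
                           nu_ff=(1.0, 0.8, 0.6, 0.4), **_COMMON)
    if family == "bias_scaling":
        return ModelParams(alpha_f=0.03, beta_f=0.8, lambda_f=2.5,
                           nu_ff=(1.0, 0.6, 0.2, 0.6), **_COMMON)
    if family in ("state_aim_scaling", "output_aim_scaling"):
        return ModelParams(lambda_f=0.9, nu_ff=(0.9, 0.6, 0.3, 0.6),
                           **_COMMON)
    raise ValueError(f"unknown family: {family!r}")


def generate_participant(spec: ModelSpec, params: ModelParams,
                         schedule: TrialSchedule,
                         noise: NoiseModel = NoiseModel(),
                         seed: int = 0,
                         participant_id: str = "p0",
                         zero_error_on_inf: bool = False) -> BehaviouralDataset:
    """Forward-simulate one participant on a schedule.

    With a zero noise model the dataset equals the noiseless model
    predictions trial for trial.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    motor = rng.normal(0.0, noise.motor_sd, size=n) if noise.motor_sd > 0 else np.zeros(n)
    arrays = schedule_arrays(schedule)
    out = predict_session(arrays, spec, params.to_vector()[None, :],
                          motor_noise=motor,
                          zero_error_on_inf=zero_error_on_inf)
    imv = out["y_t0"][0].copy()
    mp = out["y_tMP"][0].copy()
    ep = out["y_tEP"][0].copy()
    if noise.observation_sd > 0:
        imv = imv + rng.normal(0.0, noise.observation_sd, size=n)
        mp = mp + rng.normal(0.0, noise.observation_sd, size=n)
        ep = ep + rng.normal(0.0, noise.observation_sd, size=n)
    provenance = {
        "kind": "synthetic",
        "spec": spec.name,
        "params": params.to_dict(),
        "motor_sd": noise.motor_sd,
        "observation_sd": noise.observation_sd,
        "seed": seed,
        "schedule_experiment": schedule.experiment_id,
        "schedule_seed": schedule.seed,
        "zero_error_on_inf": zero_error_on_inf,
    }
    return BehaviouralDataset(schedule, imv, mp, ep, participant_id, provenance)


ParamsDistribution = Union[ModelParams, Callable[[np.random.Generator], ModelParams]]


def generate_cohort(spec: ModelSpec,
                    params_distribution: ParamsDistribution,
                    n_participants: int = 20,
                    experiment_id: int = 1,
                    noise: NoiseModel = NoiseModel(),
                    seed: int = 0,
                    schedule: Optional[TrialSchedule] = None) -> list:
    """Simulate a cohort sharing one trial-matched schedule.

    ``params_distribution`` is either a fixed :class:`ModelParams` (point
    mass) or a callable drawing one parameter set per participant from a
    seeded generator.  Noise streams are independent across participants.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if schedule is None:
        schedule = build_schedule(experiment_id, seed=seed)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_participants):
        if callable(params_distribution):
            params = params_distribution(rng)
        else:
            params = params_distribution
        part_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(generate_participant(
            spec, params, schedule, noise, seed=part_seed,
            participant_id=f"p{i:02d}"))
    return cohort


def cohort_group_average(cohort: Sequence[BehaviouralDataset]) -> pd.DataFrame:
    """Trial-wise mean of the behavioural series over a cohort.

    All datasets must share a schedule (the trial-matched design); the
    result is the group-averaged per-trial table the regression layer fits.
    """
    base = cohort[0]
    for ds in cohort[1:]:
        if len(ds.schedule) != len(base.schedule):
            raise ValueError("cohort members must share one schedule")
    frame = schedule_to_frame(base.schedule)
    frame["imv"] = np.mean([ds.imv for ds in cohort], axis=0)
    frame["mp_angle"] = np.mean([ds.mp_angle for ds in cohort], axis=0)
    frame["ep_angle"] = np.mean([ds.ep_angle for ds in cohort], axis=0)
    return frame


def write_dataset(dataset: BehaviouralDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_dataset(path, experiment_id: int = 0,
                 participant_id: str = "p0") -> BehaviouralDataset:
    from .design import schedule_from_frame

    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        float_precision="round_trip")
    schedule = schedule_from_frame(
        frame[["trial", "phase", "rotation_deg",
               "mp_uncertainty", "ep_uncertainty"]], experiment_id)
    return BehaviouralDataset(schedule,
                              frame["imv"].to_numpy(dtype=float),
                              frame["mp_angle"].to_numpy(dtype=float),
                              frame["ep_angle"].to_numpy(dtype=float),
                              participant_id)
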