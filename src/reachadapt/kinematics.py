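"""Kinematic marker extraction from 2-D reach trajectories.

Movements are 10 cm planar reaches from a start circle to a target straight
ahead, sampled at a nominal 200 Hz.  Onset is the first sample whose speed
exceeds 5% of peak speed after the hand leaves the start region; offset is
the first sample whose speed drops below 5% of peak speed after the hand
has travelled at least 9.5 cm radially from the start.  The initial
movement vector (IMV) is the signed angle (counter-clockwise positive)
between the straight start-to-target direction and the instantaneous
movement direction at onset; the endpoint hand angle is the signed angle
between the start-to-target direction and the start-to-endpoint vector at
offset.  Feedback integration is endpoint hand angle minus IMV.

Speeds come from central finite differences of position with no smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Trajectory",
    "KinematicMarks",
    "NoOnsetError",
    "NoOffsetError",
    "IncompleteReachError",
    "UndefinedAngleError",
    "detect_onset",
    "detect_offset",
    "movement_angles",
    "extract_marks",
    "make_trajectory",
]

START_RADIUS_CM = 0.25      # start circle is 0.5 cm in diameter
OFFSET_GATE_CM = 9.5        # minimum radial excursion before offset counts
SPEED_FRACTION = 0.05       # onset/offset threshold as a fraction of peak
TARGET_DISTANCE_CM = 10.0
SAMPLE_RATE_HZ = 200.0


class NoOnsetError(RuntimeError):
    """Speed never exceeded the onset threshold after leaving the start."""


class NoOffsetError(RuntimeError):
    """Speed never fell below the offset threshold after the distance gate."""


class IncompleteReachError(RuntimeError):
    """The hand never travelled the minimum 9.5 cm radial distance."""


class UndefinedAngleError(RuntimeError):
    """A zero-length movement vector has no direction."""


@dataclass(frozen=True)
class Trajectory:
    """Sampled 2-D hand path of one reach (time s, position cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    start_position: Tuple[float, float] = (0.0, 0.0)
    target_position: Tuple[float, float] = (0.0, TARGET_DISTANCE_CM)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("a trajectory needs at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != t.shape or self.y.shape != t.shape:
            raise ValueError("t, x, y must have equal length")


@dataclass(frozen=True)
class KinematicMarks:
    onset_index: int
    offset_index: int
    imv_deg: float
    ep_angle_deg: float

    def __post_init__(self):
        if self.onset_index >= self.offset_index:
            raise ValueError("onset must precede offset")

    @property
    def fb_integration_deg(self) -> float:
        return self.ep_angle_deg - self.imv_deg


def _speed(traj: Trajectory) -> np.ndarray:
    """Speed profile from central differences (one-sided at the ends)."""
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    return np.hypot(vx, vy)


def _radial_distance(traj: Trajectory) -> np.ndarray:
    sx, sy = traj.start_position
    return np.hypot(traj.x - sx, traj.y - sy)


def detect_onset(traj: Trajectory) -> int:
    """First sample with speed > 5% of peak after exiting the start region."""
    speed = _speed(traj)
    dist = _radial_distance(traj)
    threshold = SPEED_FRACTION * speed.max()
    outside = np.flatnonzero(dist > START_RADIUS_CM)
    if outside.size == 0:
        raise NoOnsetError("hand never left the start region")
    candidates = np.flatnonzero((speed > threshold)
                                & (np.arange(speed.size) >= outside[0]))
    if candidates.size == 0:
        raise NoOnsetError("speed never exceeded the onset threshold")
    return int(candidates[0])


def detect_offset(traj: Trajectory) -> int:
    """First sample with speed < 5% of peak after the 9.5 cm radial gate."""
    speed = _speed(traj)
    dist = _radial_distance(traj)
    threshold = SPEED_FRACTION * speed.max()
    past_gate = np.flatnonzero(dist >= OFFSET_GATE_CM)
    if past_gate.size == 0:
        raise IncompleteReachError("reach never travelled 9.5 cm")
    candidates = np.flatnonzero((speed < threshold)
                                & (np.arange(speed.size) >= past_gate[0]))
    if candidates.size == 0:
        raise NoOffsetError("speed never dropped below the offset threshold")
    return int(candidates[0])


def _signed_angle_deg(optimal: np.ndarray, vec: np.ndarray) -> float:
    norm = math.hypot(*vec)
    if norm == 0.0:
        raise UndefinedAngleError("zero-length movement vector")
    # CCW-positive angle of `vec` relative to `optimal`
    cross = optimal[0] * vec[1] - optimal[1] * vec[0]
    dot = optimal[0] * vec[0] + optimal[1] * vec[1]
    return math.degrees(math.atan2(cross, dot))


def movement_angles(traj: Trajectory, onset_index: int, offset_index: int,
                    method: str = "velocity",
                    chord_samples: int = 10) -> Tuple[float, float]:
    """(IMV, endpoint hand angle) in degrees, counter-clockwise positive.

    By default the IMV uses the instantaneous velocity direction at the
    onset sample (the standard reading of "movement vector at onset");
    ``method="chord"`` instead uses the displacement over the first
    ``chord_samples`` samples after onset, which is robust to sampling
    noise.  The endpoint angle always uses the start-to-endpoint vector at
    the offset sample.
    """
    sx, sy = traj.start_position
    tx, ty = traj.target_position
    optimal = np.array([tx - sx, ty - sy])
    if method == "velocity":
        vx = np.gradient(traj.x, traj.t)
        vy = np.gradient(traj.y, traj.t)
        early = np.array([vx[onset_index], vy[onset_index]])
    elif method == "chord":
        j = min(onset_index + chord_samples, len(traj.t) - 1)
        early = np.array([traj.x[j] - traj.x[onset_index],
                          traj.y[j] - traj.y[onset_index]])
    else:
        raise ValueError(f"unknown method: {method!r}")
    imv = _signed_angle_deg(optimal, early)
    endpoint = np.array([traj.x[offset_index] - sx, traj.y[offset_index] - sy])
    ep = _signed_angle_deg(optimal, endpoint)
    return imv, ep


def extract_marks(traj: Trajectory, method: str = "velocity",
                  chord_samples: int = 10) -> "KinematicMarks":
    """Onset, offset and both hand angles of one trajectory."""
    onset = detect_onset(traj)
    offset = detect_offset(traj)
    imv, ep = movement_angles(traj, onset, offset, method=method,
                              chord_samples=chord_samples)
    return KinematicMarks(onset, offset, imv, ep)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _direction(angle_deg: float) -> np.ndarray:
    # unit vector rotated CCW-positive away from the +y target direction
    a = math.radians(angle_deg)
    return np.array([-math.sin(a), math.cos(a)])


def make_trajectory(imv_deg: float, ep_angle_deg: float,
                    correction_onset_cm: float = 4.0,
                    dt: float = 1.0 / SAMPLE_RATE_HZ,
                    seed: Optional[int] = None,
                    jitter_cm: float = 0.0,
                    duration_s: float = 0.6,
                    dwell_s: float = 0.15) -> Trajectory:
    """Synthetic two-segment reach fixture with known angles.

    Builds a smooth 10 cm reach whose early movement direction equals
    ``imv_deg`` and whose endpoint lies at ``ep_angle_deg``, blending from
    the initial heading to the endpoint from ``correction_onset_cm``
    outward, with a minimum-jerk speed profile and a terminal dwell.  Used
    as the round-trip test surface for the detectors.
    """
    if abs(imv_deg) >= 90 or abs(ep_angle_deg) >= 90:
        raise ValueError("angles must lie within (-90, 90) degrees")
    n_move = int(round(duration_s / dt))
    tau = np.linspace(0.0, 1.0, n_move)
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5  # min-jerk path fraction
    arc = s * TARGET_DISTANCE_CM
    u0 = _direction(imv_deg)
    u1 = _direction(ep_angle_deg)
    w = _smoothstep((arc - correction_onset_cm)
                    / (TARGET_DISTANCE_CM - correction_onset_cm))
    pts = (1.0 - w)[:, None] * arc[:, None] * u0 + w[:, None] * arc[:, None] * u1
    n_dwell = int(round(dwell_s / dt))
    pts = np.vstack([pts, np.repeat(pts[-1:, :], n_dwell, axis=0)])
    if jitter_cm > 0:
        # smooth low-frequency positional wobble (physical hand tremor),
        # not per-sample white noise, which at 200 Hz would swamp the
        # finite-difference speed estimate
        rng = np.random.default_rng(seed)
        n = len(pts)
        knot_step = 30  # one knot per 150 ms
        knots = np.arange(0, n + knot_step, knot_step)
        sample_idx = np.arange(n)
        wobble = np.column_stack([
            np.interp(sample_idx, knots,
                      rng.normal(0.0, jitter_cm, size=len(knots)))
            for _ in range(2)])
        pts = pts + wobble
    t = np.arange(len(pts)) * dt
    return Trajectory(t, pts[:, 0], pts[:, 1])
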