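"""State-space models of feedforward adaptation with midpoint feedback.

Within each trial the motor output is defined at three time points: reach
initiation (t0), midpoint crossing (tMP) and endpoint (tEP).  The output is
the sum of a feedforward command, fixed at t0, and a feedback command that
is zero at t0 and corrects a fraction of the midpoint cursor error:

    y(n, t)    = y_ff(n) + y_fb(n, t)           (+ y_aim(n) for output-aim)
    y_fb(n,t0) = 0
    d(n,tMP)   = y(n,t0) + r(n)
    y_fb(n,tMP)= -x_fb(n) * d(n,tMP) * eta[level_MP(n)]
    d(n,tEP)   = y(n,tMP) + r(n)
    y(n,tEP)   = y(n,tMP)

where r(n) is the imposed rotation and eta is a 4-vector of feedback
uncertainty scalings, one entry per level (L, M, H, INF).  Between trials
the feedback gain adapts from endpoint error, insensitive to uncertainty:

    x_fb(n+1) = beta_fb * x_fb(n) + alpha_fb * d(n,tEP)

The feedforward plan is carried by one state (x) or by fast+slow states
whose outputs sum.  The slow state is never modulated by uncertainty:

    x_s(n+1) = beta_s*x_s + alpha_s*d(n,tMP)
               + alpha_s*[d(n,tEP) - y_fb(n,tMP)] + lambda_s

The five model families place the sensory-uncertainty scaling nu (a
4-vector, with gamma weighting midpoint versus endpoint events) at five
different loci of the fast-state update:

    error-scaling:     b*x + g*nu[mp]*a*d_MP + (1-g)*nu[ep]*a*d_EP' + l
    retention-scaling: [g*nu[mp] + (1-g)*nu[ep]]*b*x + a*d_MP + a*d_EP' + l
    bias-scaling:      b*x + a*d_MP + a*d_EP' + [g*nu[mp] + (1-g)*nu[ep]]*l
    state-aim:         [g*nu[mp] + (1-g)*nu[ep]]*l           (memoryless)
    output-aim:        fast state unused; y_aim(n) =
                       [g*nu[mp(n-1)] + (1-g)*nu[ep(n-1)]]*l  added to output

with d_EP' = d(n,tEP) - y_fb(n,tMP).  Trials without a feedback event
(baseline's continuous veridical display, washout) contribute no error
terms and no feedback command; their scaling factors index the INF entry.
Adaptation trials at the no-feedback level INF are treated literally (the
latent error scaled by the fitted nu/eta INF entries) unless
``zero_error_on_inf`` forces those terms to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .design import TrialSchedule, TrialSpec, UncertaintyLevel

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ModelSpec",
    "ModelParams",
    "SessionState",
    "TrialOutputs",
    "ContractViolation",
    "feedforward_output",
    "midpoint_error",
    "feedback_command",
    "endpoint_error",
    "update_feedback_gain",
    "update_slow_state",
    "update_fast_state",
    "aim_output",
    "simulate_trial",
    "simulate_session",
    "schedule_arrays",
    "predict_session",
    "predict_session_reference",
]

FAMILIES = (
    "error_scaling",
    "retention_scaling",
    "bias_scaling",
    "state_aim_scaling",
    "output_aim_scaling",
)
AIM_FAMILIES = ("state_aim_scaling", "output_aim_scaling")

# Canonical flat parameter order used by the fitting machinery.
PARAM_NAMES = (
    "alpha_f", "beta_f", "lambda_f",
    "alpha_s", "beta_s", "lambda_s",
    "alpha_fb", "beta_fb", "x_fb_init",
    "nu_ff_L", "nu_ff_M", "nu_ff_H", "nu_ff_INF",
    "nu_fb_L", "nu_fb_M", "nu_fb_H", "nu_fb_INF",
    "gamma",
)


class ContractViolation(RuntimeError):
    """An operation was called outside its model-family contract."""


# Latent states are clipped at this magnitude so that candidates in the
# divergent region of the parameter space (|beta_fb| > 1 is inside the
# bound table) keep a finite, ordered objective instead of overflowing.
STATE_CLIP = 1e8


def _clip(value):
    return np.clip(value, -STATE_CLIP, STATE_CLIP)


@dataclass(frozen=True)
class ModelSpec:
    """Which model: scaling family, number of states, bound regime."""

    family: str
    n_states: int = 2
    nonneg: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        if self.n_states not in (1, 2):
            raise ValueError("n_states must be 1 or 2")
        if self.nonneg and self.n_states != 2:
            raise ValueError("non-negative variants exist only for two-state models")

    @property
    def name(self) -> str:
        tag = f"{self.family}-{self.n_states}state"
        return tag + ("-nonneg" if self.nonneg else "")


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of one model.

    For the aim families ``lambda_f`` is the aim amplitude of the
    memoryless term; their fast state has no error/retention dynamics, so
    ``alpha_f``/``beta_f`` are unused there.  ``nu_ff`` and ``nu_fb`` are
    ordered (L, M, H, INF).
    """

    alpha_f: float = 0.0
    beta_f: float = 0.0
    lambda_f: float = 0.0
    alpha_s: float = 0.0
    beta_s: float = 0.0
    lambda_s: float = 0.0
    alpha_fb: float = 0.0
    beta_fb: float = 0.0
    x_fb_init: float = 0.0
    nu_ff: tuple = (1.0, 1.0, 1.0, 1.0)
    nu_fb: tuple = (1.0, 1.0, 1.0, 1.0)
    gamma: float = 0.5

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.alpha_f, self.beta_f, self.lambda_f,
             self.alpha_s, self.beta_s, self.lambda_s,
             self.alpha_fb, self.beta_fb, self.x_fb_init,
             *self.nu_ff, *self.nu_fb, self.gamma], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "ModelParams":
        v = np.asarray(vec, dtype=float)
        if v.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} entries, got {v.shape}")
        return cls(
            alpha_f=v[0], beta_f=v[1], lambda_f=v[2],
            alpha_s=v[3], beta_s=v[4], lambda_s=v[5],
            alpha_fb=v[6], beta_fb=v[7], x_fb_init=v[8],
            nu_ff=tuple(v[9:13]), nu_fb=tuple(v[13:17]), gamma=v[17])

    def to_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.to_vector()))


@dataclass
class SessionState:
    """Evolving latent variables across trials."""

    x_fast: float = 0.0
    x_slow: float = 0.0
    x_fb: float = 0.0


@dataclass(frozen=True)
class TrialOutputs:
    """Motor outputs and errors of one simulated trial (degrees)."""

    y_t0: float
    y_tMP: float
    y_tEP: float
    delta_MP: float
    delta_EP: float
    y_fb_MP: float
    y_aim: float = 0.0


def _lvl_index(level) -> int:
    """Scaling index of a feedback event; absent events use the INF entry."""
    return 3 if level is None else int(level)


# ---------------------------------------------------------------------------
# Elementary within- and between-trial operations


def feedforward_output(state: SessionState, spec: ModelSpec) -> float:
    """y_ff(n): the fast state, plus the slow state in two-state models."""
    if spec.n_states == 2:
        return state.x_fast + state.x_slow
    return state.x_fast


def midpoint_error(y_t0: float, rotation_deg: float) -> float:
    """Cursor error at midpoint: d(n,tMP) = y(n,t0) + r(n)."""
    return y_t0 + rotation_deg


def feedback_command(x_fb: float, delta_MP: float, nu_fb: Sequence[float],
                     mp_level) -> float:
    """Midpoint correction -x_fb * d_MP * eta[level]; zero without an event."""
    if mp_level is None:
        return 0.0
    return -x_fb * delta_MP * nu_fb[_lvl_index(mp_level)]


def endpoint_error(y_tMP: float, rotation_deg: float) -> float:
    """Cursor error at endpoint: d(n,tEP) = y(n,tMP) + r(n)."""
    return y_tMP + rotation_deg


def update_feedback_gain(x_fb: float, delta_EP: float,
                         params: ModelParams) -> float:
    """x_fb(n+1) = beta_fb*x_fb(n) + alpha_fb*d(n,tEP); uncertainty-blind."""
    return params.beta_fb * x_fb + params.alpha_fb * delta_EP


def update_slow_state(x_slow: float, delta_MP: float, delta_EP: float,
                      y_fb_MP: float, params: ModelParams,
                      spec: ModelSpec) -> float:
    """Slow-state update; independent of sensory uncertainty."""
    if spec.n_states != 2:
        raise ContractViolation("slow state exists only in two-state models")
    return (params.beta_s * x_slow
            + params.alpha_s * delta_MP
            + params.alpha_s * (delta_EP - y_fb_MP)
            + params.lambda_s)


def update_fast_state(x_fast: float, delta_MP: float, delta_EP: float,
                      y_fb_MP: float, mp_level, ep_level,
                      params: ModelParams, spec: ModelSpec) -> float:
    """Fast-state update, dispatching on the scaling family.

    ``delta_MP``/``delta_EP`` are the error signals actually available on
    the trial (zero when there was no feedback event); levels index the
    ``nu_ff`` scaling vector, with absent events mapped to the INF entry.
    """
    nu = params.nu_ff
    fmp = nu[_lvl_index(mp_level)]
    fep = nu[_lvl_index(ep_level)]
    g = params.gamma
    mix = g * fmp + (1.0 - g) * fep
    e_ep = delta_EP - y_fb_MP
    fam = spec.family
    if fam == "error_scaling":
        return (params.beta_f * x_fast
                + g * fmp * params.alpha_f * delta_MP
                + (1.0 - g) * fep * params.alpha_f * e_ep
                + params.lambda_f)
    if fam == "retention_scaling":
        return (mix * params.beta_f * x_fast
                + params.alpha_f * delta_MP
                + params.alpha_f * e_ep
                + params.lambda_f)
    if fam == "bias_scaling":
        return (params.beta_f * x_fast
                + params.alpha_f * delta_MP
                + params.alpha_f * e_ep
                + mix * params.lambda_f)
    if fam == "state_aim_scaling":
        return mix * params.lambda_f
    if fam == "output_aim_scaling":
        # uncertainty never touches the states; the aim term is added to
        # the motor output instead (aim_output) and the fast state is inert
        return 0.0
    raise ValueError(f"unknown family: {fam!r}")


def aim_output(mp_level_prev, ep_level_prev, params: ModelParams,
               spec: ModelSpec) -> float:
    """Output-aim term driven by the previous trial's uncertainty levels."""
    if spec.family != "output_aim_scaling":
        raise ContractViolation("aim output exists only in output-aim models")
    nu = params.nu_ff
    g = params.gamma
    return (g * nu[_lvl_index(mp_level_prev)]
            + (1.0 - g) * nu[_lvl_index(ep_level_prev)]) * params.lambda_f


# ---------------------------------------------------------------------------
# Trial and session simulation (reference scalar path)


def simulate_trial(state: SessionState, trial: TrialSpec,
                   prev_trial: Optional[TrialSpec], params: ModelParams,
                   spec: ModelSpec, motor_noise: float = 0.0,
                   zero_error_on_inf: bool = False):
    """Run one trial: outputs at t0/tMP/tEP and the next-trial state.

    ``motor_noise`` is execution noise added to y(n,t0) before the midpoint
    error is computed, so it propagates through the feedback correction and
    the learning updates as it would in a closed-loop participant.
    """
    adapt = trial.phase == "adaptation"
    y_aim = 0.0
    if spec.family == "output_aim_scaling":
        # driven by the previous trial's levels on every trial; absent
        # events (first trial, baseline, washout) index the INF entry
        pmp = prev_trial.mp_uncertainty if prev_trial is not None else None
        pep = prev_trial.ep_uncertainty if prev_trial is not None else None
        y_aim = aim_output(pmp, pep, params, spec)

    y_t0 = feedforward_output(state, spec) + y_aim + motor_noise
    r = trial.rotation_deg
    d_mp = midpoint_error(y_t0, r)

    mp_blank = (trial.mp_uncertainty is None
                or trial.mp_uncertainty == UncertaintyLevel.INF)
    ep_blank = (trial.ep_uncertainty is None
                or trial.ep_uncertainty == UncertaintyLevel.INF)

    if adapt and not (zero_error_on_inf and mp_blank):
        y_fb = feedback_command(state.x_fb, d_mp, params.nu_fb,
                                trial.mp_uncertainty)
    else:
        y_fb = 0.0
    y_mp = y_t0 + y_fb
    d_ep = endpoint_error(y_mp, r)
    y_ep = y_mp  # no further command between the midpoint correction and tEP

    # learning signals: zero outside adaptation; optionally zero on INF events
    err_mp = d_mp if (adapt and not (zero_error_on_inf and mp_blank)) else 0.0
    ep_active = adapt and not (zero_error_on_inf and ep_blank)
    err_ep = d_ep if ep_active else 0.0
    err_fb = y_fb if ep_active else 0.0  # enters only via (d_EP - y_fb)

    x_fast = float(_clip(update_fast_state(
        state.x_fast, err_mp, err_ep, err_fb,
        trial.mp_uncertainty, trial.ep_uncertainty, params, spec)))
    if spec.n_states == 2:
        x_slow = float(_clip(update_slow_state(state.x_slow, err_mp, err_ep,
                                               err_fb, params, spec)))
    else:
        x_slow = 0.0
    x_fb = float(_clip(update_feedback_gain(state.x_fb, err_ep, params)))

    outputs = TrialOutputs(y_t0=y_t0, y_tMP=y_mp, y_tEP=y_ep,
                           delta_MP=d_mp, delta_EP=d_ep, y_fb_MP=y_fb,
                           y_aim=y_aim)
    return SessionState(x_fast, x_slow, x_fb), outputs


def simulate_session(schedule: TrialSchedule, params: ModelParams,
                     spec: ModelSpec,
                     initial_state: Optional[SessionState] = None,
                     motor_noise=None,
                     zero_error_on_inf: bool = False) -> list:
    """Fold :func:`simulate_trial` over a schedule; deterministic.

    ``motor_noise`` may be a per-trial array of execution-noise draws.
    """
    state = initial_state if initial_state is not None else SessionState(
        0.0, 0.0, params.x_fb_init)
    if motor_noise is None:
        motor_noise = np.zeros(len(schedule))
    outputs = []
    prev = None
    for n, trial in enumerate(schedule):
        state, out = simulate_trial(state, trial, prev, params, spec,
                                    motor_noise=float(motor_noise[n]),
                                    zero_error_on_inf=zero_error_on_inf)
        outputs.append(out)
        prev = trial
    return outputs


# ---------------------------------------------------------------------------
# Vectorized engine: simulates S parameter vectors simultaneously, used by
# the fitting machinery (differential evolution populations) and by the
# synthetic-participant generator.


def schedule_arrays(schedule: TrialSchedule) -> dict:
    """Precompute per-trial arrays the vectorized engine consumes."""
    n = len(schedule)
    r = np.zeros(n)
    mp_idx = np.full(n, 3, dtype=np.int64)
    ep_idx = np.full(n, 3, dtype=np.int64)
    adapt = np.zeros(n, dtype=bool)
    mp_blank = np.ones(n, dtype=bool)
    ep_blank = np.ones(n, dtype=bool)
    phase = []
    for i, t in enumerate(schedule):
        r[i] = t.rotation_deg
        adapt[i] = t.phase == "adaptation"
        mp_idx[i] = _lvl_index(t.mp_uncertainty)
        ep_idx[i] = _lvl_index(t.ep_uncertainty)
        mp_blank[i] = t.mp_uncertainty is None or t.mp_uncertainty == UncertaintyLevel.INF
        ep_blank[i] = t.ep_uncertainty is None or t.ep_uncertainty == UncertaintyLevel.INF
        phase.append(t.phase)
    return {"r": r, "mp_idx": mp_idx, "ep_idx": ep_idx, "adapt": adapt,
            "mp_blank": mp_blank, "ep_blank": ep_blank,
            "phase": np.array(phase)}


try:  # optional jitted kernel; the numpy path below is the reference
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

_FAM_CODE = {f: i for i, f in enumerate(FAMILIES)}


def _kernel_py(r, mp_idx, ep_idx, adapt, mp_off, ep_off, fam, two_state,
               theta, noise, y0_out, ymp_out):
    S, N = theta.shape[0], r.shape[0]
    clip = STATE_CLIP
    for s in range(S):
        af, bf, lf = theta[s, 0], theta[s, 1], theta[s, 2]
        as_, bs, ls = theta[s, 3], theta[s, 4], theta[s, 5]
        afb, bfb = theta[s, 6], theta[s, 7]
        xfb = theta[s, 8]
        g = theta[s, 17]
        xf = 0.0
        xs = 0.0
        pmp, pep = 3, 3
        for n in range(N):
            mpi, epi = mp_idx[n], ep_idx[n]
            if fam == 4:
                aim = (g * theta[s, 9 + pmp]
                       + (1.0 - g) * theta[s, 9 + pep]) * lf
            else:
                aim = 0.0
            y0 = xf + xs + aim + noise[n]
            dmp = y0 + r[n]
            mp_on = adapt[n] and not mp_off[n]
            yfb = -xfb * dmp * theta[s, 13 + mpi] if mp_on else 0.0
            ymp = y0 + yfb
            dep = ymp + r[n]
            e_mp = dmp if mp_on else 0.0
            ep_on = adapt[n] and not ep_off[n]
            e_ep = dep if ep_on else 0.0
            e_term = (dep - yfb) if ep_on else 0.0
            fmp = theta[s, 9 + mpi]
            fep = theta[s, 9 + epi]
            mix = g * fmp + (1.0 - g) * fep
            if fam == 0:
                xf = bf * xf + g * fmp * af * e_mp \
                    + (1.0 - g) * fep * af * e_term + lf
            elif fam == 1:
                xf = mix * bf * xf + af * e_mp + af * e_term + lf
            elif fam == 2:
                xf = bf * xf + af * e_mp + af * e_term + mix * lf
            elif fam == 3:
                xf = mix * lf
            else:
                xf = 0.0
            xf = min(max(xf, -clip), clip)
            if two_state:
                xs = bs * xs + as_ * e_mp + as_ * e_term + ls
                xs = min(max(xs, -clip), clip)
            xfb = bfb * xfb + afb * e_ep
            xfb = min(max(xfb, -clip), clip)
            y0_out[s, n] = y0
            ymp_out[s, n] = ymp
            pmp, pep = mpi, epi


_kernel = _njit(cache=True)(_kernel_py) if _njit is not None else _kernel_py


def predict_session(arrays: dict, spec: ModelSpec, theta: np.ndarray,
                    motor_noise=None, zero_error_on_inf: bool = False):
    """Simulate S candidate parameter vectors over one schedule at once.

    ``theta`` has shape (S, 18) in :data:`PARAM_NAMES` order.  Returns a
    dict of (S, N) arrays ``y_t0``, ``y_tMP``, ``y_tEP``.  Each row is
    bitwise-identical to the scalar :func:`simulate_session` path.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    r = arrays["r"]
    N = r.shape[0]
    if motor_noise is None:
        motor_noise = np.zeros(N)
    mp_off = (np.asarray(arrays["mp_blank"]) if zero_error_on_inf
              else np.zeros(N, dtype=bool))
    ep_off = (np.asarray(arrays["ep_blank"]) if zero_error_on_inf
              else np.zeros(N, dtype=bool))
    S = theta.shape[0]
    y0_out = np.empty((S, N))
    ymp_out = np.empty((S, N))
    _kernel(r, arrays["mp_idx"], arrays["ep_idx"], arrays["adapt"],
            mp_off, ep_off, _FAM_CODE[spec.family], spec.n_states == 2,
            theta, np.asarray(motor_noise, dtype=float), y0_out, ymp_out)
    return {"y_t0": y0_out, "y_tMP": ymp_out, "y_tEP": ymp_out}


def predict_session_reference(arrays: dict, spec: ModelSpec, theta: np.ndarray,
                              motor_noise=None,
                              zero_error_on_inf: bool = False):
    """Pure-numpy implementation of :func:`predict_session` (reference)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    S = theta.shape[0]
    r = arrays["r"]
    N = r.shape[0]
    mp_idx, ep_idx = arrays["mp_idx"], arrays["ep_idx"]
    adapt = arrays["adapt"]
    mp_blank, ep_blank = arrays["mp_blank"], arrays["ep_blank"]
    if motor_noise is None:
        motor_noise = np.zeros(N)

    af, bf, lf = theta[:, 0], theta[:, 1], theta[:, 2]
    as_, bs, ls = theta[:, 3], theta[:, 4], theta[:, 5]
    afb, bfb, xfb0 = theta[:, 6], theta[:, 7], theta[:, 8]
    nu = theta[:, 9:13]
    eta = theta[:, 13:17]
    g = theta[:, 17]
    fam = spec.family
    two_state = spec.n_states == 2

    xf = np.zeros(S)
    xs = np.zeros(S)
    xfb = xfb0.copy()
    y0_out = np.empty((S, N))
    ymp_out = np.empty((S, N))

    prev_mpi, prev_epi = 3, 3
    for n in range(N):
        is_adapt = bool(adapt[n])
        mpi, epi = int(mp_idx[n]), int(ep_idx[n])
        mp_off = zero_error_on_inf and mp_blank[n]
        ep_off = zero_error_on_inf and ep_blank[n]

        if fam == "output_aim_scaling":
            aim = (g * nu[:, prev_mpi] + (1.0 - g) * nu[:, prev_epi]) * lf
        else:
            aim = 0.0
        y0 = xf + xs + aim + motor_noise[n]
        d_mp = y0 + r[n]
        if is_adapt and not mp_off:
            yfb = -xfb * d_mp * eta[:, mpi]
        else:
            yfb = np.zeros(S)
        ymp = y0 + yfb
        d_ep = ymp + r[n]

        e_mp = d_mp if (is_adapt and not mp_off) else 0.0
        ep_active = is_adapt and not ep_off
        e_ep = d_ep if ep_active else 0.0
        e_ep_term = (d_ep - yfb) if ep_active else 0.0

        fmp = nu[:, mpi]
        fep = nu[:, epi]
        mix = g * fmp + (1.0 - g) * fep
        if fam == "error_scaling":
            xf = bf * xf + g * fmp * af * e_mp + (1.0 - g) * fep * af * e_ep_term + lf
        elif fam == "retention_scaling":
            xf = mix * bf * xf + af * e_mp + af * e_ep_term + lf
        elif fam == "bias_scaling":
            xf = bf * xf + af * e_mp + af * e_ep_term + mix * lf
        elif fam == "state_aim_scaling":
            xf = mix * lf
        elif fam == "output_aim_scaling":
            xf = np.zeros(S)
        else:  # pragma: no cover
            raise ValueError(f"unknown family: {fam!r}")
        xf = _clip(xf)
        if two_state:
            xs = _clip(bs * xs + as_ * e_mp + as_ * e_ep_term + ls)
        xfb = _clip(bfb * xfb + afb * e_ep)

        y0_out[:, n] = y0
        ymp_out[:, n] = ymp
        prev_mpi, prev_epi = mpi, epi

    return {"y_t0": y0_out, "y_tMP": ymp_out, "y_tEP": ymp_out}
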