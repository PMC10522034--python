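"""Per-participant parameter estimation by bounded global optimization.

The objective is the sum of squared differences between model-predicted and
observed hand angles at midpoint and endpoint over the fitted trials,

    E = sum_i [y_pred(i,tMP) - y_obs(i,tMP)]^2
        + sum_i [y_pred(i,tEP) - y_obs(i,tEP)]^2

minimised with SciPy's differential evolution inside per-model parameter
bounds.  By default the fitted trials are the adaptation and washout phases
(washout constrains retention); baseline can be included via ``phases``.
The variance explained is pooled over both series, R^2 = 1 - E / TSS with
TSS taken about the pooled mean, and n for the information criterion is the
number of residuals entering E (two per fitted trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .compare import bic
from .models import (PARAM_NAMES, ModelParams, ModelSpec, predict_session,
                     schedule_arrays)
from .synth import BehaviouralDataset

__all__ = [
    "param_bounds",
    "count_free_parameters",
    "objective",
    "OptimizerConfig",
    "FitResult",
    "fit_participant",
]

DEFAULT_PHASES = ("adaptation", "washout")

_NU_FF = ["nu_ff_L", "nu_ff_M", "nu_ff_H", "nu_ff_INF"]
_NU_FB = ["nu_fb_L", "nu_fb_M", "nu_fb_H", "nu_fb_INF"]


def param_bounds(spec: ModelSpec) -> dict:
    """(lower, upper) bounds per parameter for one model variant.

    Fixed parameters are encoded as lower == upper; parameters absent from
    the variant are omitted.  The aim families carry no fast-state
    error/retention dynamics; their ``lambda_f`` is the aim amplitude,
    bounded (0, 1) and widened to (0, 10) in the non-negative variant.
    """
    fam = spec.family
    bounds: dict = {}
    if fam in ("error_scaling", "retention_scaling", "bias_scaling"):
        bounds["alpha_f"] = (0.0, 1.0)
        bounds["beta_f"] = (0.0, 1.0)
        bounds["lambda_f"] = (0.0, 10.0) if spec.nonneg else (-10.0, 10.0)
        nu_fb = (0.0, 1.0) if fam != "bias_scaling" else (-1.0, 1.0)
        for name in _NU_FB:
            bounds[name] = nu_fb
        if fam == "bias_scaling" and spec.nonneg:
            bounds["nu_fb_INF"] = (0.0, 1.0)
    else:  # aim families
        bounds["lambda_f"] = (0.0, 10.0) if spec.nonneg else (0.0, 1.0)
        nu_fb = (0.0, 20.0) if spec.nonneg else (-20.0, 20.0)
        for name in _NU_FB:
            bounds[name] = nu_fb
    if spec.n_states == 2:
        bounds["alpha_s"] = (0.0, 1.0)
        bounds["beta_s"] = (0.0, 1.0)
        bounds["lambda_s"] = (0.0, 0.0)  # slow state carries no free bias
    bounds["alpha_fb"] = (0.0, 1.0)
    bounds["beta_fb"] = (-10.0, 10.0)
    bounds["x_fb_init"] = (-2.0, 2.0)
    for name in _NU_FF:
        bounds[name] = (0.0, 1.0)
    bounds["gamma"] = (0.0, 1.0)
    return bounds


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of bound entries with lower < upper (the k of the BIC)."""
    return sum(lo < hi for lo, hi in param_bounds(spec).values())


def _template_vector(bounds: dict) -> Tuple[np.ndarray, list, np.ndarray]:
    """Full 18-slot template with fixed/absent values, plus free-slot info."""
    template = np.zeros(len(PARAM_NAMES))
    free_idx, free_bounds = [], []
    for i, name in enumerate(PARAM_NAMES):
        if name not in bounds:
            continue
        lo, hi = bounds[name]
        if lo == hi:
            template[i] = lo
        else:
            free_idx.append(i)
            free_bounds.append((lo, hi))
    return template, free_idx, np.array(free_bounds)


def _phase_mask(arrays: dict, phases: Sequence[str]) -> np.ndarray:
    return np.isin(arrays["phase"], list(phases))


def objective(params: ModelParams, spec: ModelSpec,
              dataset: BehaviouralDataset,
              phases: Sequence[str] = DEFAULT_PHASES,
              zero_error_on_inf: bool = False) -> float:
    """E: summed squared MP and EP residuals over the fitted trials."""
    if len(dataset.imv) != len(dataset.schedule):
        raise ValueError("dataset length does not match its schedule")
    arrays = schedule_arrays(dataset.schedule)
    mask = _phase_mask(arrays, phases)
    out = predict_session(arrays, spec, params.to_vector()[None, :],
                          zero_error_on_inf=zero_error_on_inf)
    res_mp = out["y_tMP"][0, mask] - dataset.mp_angle[mask]
    res_ep = out["y_tEP"][0, mask] - dataset.ep_angle[mask]
    return float(res_mp @ res_mp + res_ep @ res_ep)


@dataclass(frozen=True)
class OptimizerConfig:
    """Differential-evolution settings (the algorithm's own defaults are a
    reasonable starting point; these trade precision for runtime)."""

    maxiter: int = 600
    popsize: int = 8
    tol: float = 1e-10
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    init: str = "latinhypercube"
    polish: bool = True
    polish_maxiter: int = 300
    polish_candidates: int = 10  # best population members refined locally
    restarts: int = 2


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    params: ModelParams
    E: float
    r2: float
    n_points: int
    k: int
    bic: float
    seed: int
    converged: bool
    restart_log: tuple = ()  # (seed, E) per restart

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"FitResult({self.spec.name}, E={self.E:.4g}, "
                f"R2={self.r2:.4f}, BIC={self.bic:.2f})")


def fit_participant(spec: ModelSpec, dataset: BehaviouralDataset,
                    seed: int = 0,
                    optimizer: OptimizerConfig = OptimizerConfig(),
                    phases: Sequence[str] = DEFAULT_PHASES,
                    zero_error_on_inf: bool = False,
                    x0: Optional[ModelParams] = None) -> FitResult:
    """Fit one model variant to one participant's MP/EP hand angles.

    Seeded and deterministic: the same seed yields the same result.  With
    ``optimizer.restarts > 1`` the search is repeated from distinct seeds
    and the lowest-E solution kept.  ``x0`` seeds one population member
    with a known parameter vector (its objective then upper-bounds the
    returned E).
    """
    bounds = param_bounds(spec)
    template, free_idx, free_bounds = _template_vector(bounds)
    arrays = schedule_arrays(dataset.schedule)
    mask = _phase_mask(arrays, phases)
    obs_mp = dataset.mp_angle[mask]
    obs_ep = dataset.ep_angle[mask]

    def evaluate(x: np.ndarray) -> np.ndarray:
        # x: (k,) or (k, S) per SciPy's vectorized convention
        x2 = np.atleast_2d(x.T if x.ndim == 2 else x)
        theta = np.tile(template, (x2.shape[0], 1))
        theta[:, free_idx] = x2
        out = predict_session(arrays, spec, theta,
                              zero_error_on_inf=zero_error_on_inf)
        res_mp = out["y_tMP"][:, mask] - obs_mp
        res_ep = out["y_tEP"][:, mask] - obs_ep
        with np.errstate(over="ignore", invalid="ignore"):
            e = np.einsum("ij,ij->i", res_mp, res_mp) + \
                np.einsum("ij,ij->i", res_ep, res_ep)
        e = np.where(np.isfinite(e), e, 1e300)
        return e if x.ndim == 2 else float(e[0])

    def polish(x0: np.ndarray):
        """Bounded local refinement with a batched central-difference
        gradient (one vectorized engine call per gradient evaluation)."""
        k = len(x0)
        span = free_bounds[:, 1] - free_bounds[:, 0]
        h = 1e-6 * np.maximum(span, 1.0)

        def fun_and_grad(x):
            X = np.tile(x, (2 * k + 1, 1))
            for i in range(k):
                X[1 + i, i] = min(x[i] + h[i], free_bounds[i, 1])
                X[1 + k + i, i] = max(x[i] - h[i], free_bounds[i, 0])
            e = evaluate(X.T)
            grad = np.array([(e[1 + i] - e[1 + k + i])
                             / (X[1 + i, i] - X[1 + k + i, i])
                             for i in range(k)])
            return float(e[0]), grad

        return minimize(fun_and_grad, x0, jac=True, method="L-BFGS-B",
                        bounds=free_bounds,
                        options={"maxiter": optimizer.polish_maxiter})

    rng = np.random.default_rng(seed)
    restart_seeds = [seed] + [int(rng.integers(0, 2**31 - 1))
                              for _ in range(optimizer.restarts - 1)]
    best_x, best_fun, best_success = None, np.inf, False
    log = []
    x0_free = None
    if x0 is not None:
        vec0 = x0.to_vector()
        x0_free = np.clip(vec0[free_idx], free_bounds[:, 0],
                          free_bounds[:, 1])
    for rs in restart_seeds:
        result = differential_evolution(
            evaluate, bounds=list(map(tuple, free_bounds)),
            seed=rs, maxiter=optimizer.maxiter, popsize=optimizer.popsize,
            tol=optimizer.tol, mutation=optimizer.mutation,
            recombination=optimizer.recombination, init=optimizer.init,
            x0=x0_free,
            polish=False, vectorized=True, updating="deferred")
        x, fun, success = result.x, float(result.fun), bool(result.success)
        if optimizer.polish:
            order = np.argsort(result.population_energies)
            starts = result.population[order[:optimizer.polish_candidates]]
            for x0 in starts:
                local = polish(x0)
                if local.fun < fun:
                    x, fun = local.x, float(local.fun)
        log.append((rs, fun))
        if fun < best_fun:
            best_x, best_fun, best_success = x, fun, success

    vec = template.copy()
    vec[free_idx] = best_x
    params = ModelParams.from_vector(vec)
    E = best_fun
    obs = np.concatenate([obs_mp, obs_ep])
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - E / tss if tss > 0 else float("nan")
    n = obs.size
    k = len(free_idx)
    score = bic(n, k, r2) if r2 < 1.0 else float("-inf")
    return FitResult(spec=spec, params=params, E=E, r2=r2, n_points=n,
                     k=k, bic=score, seed=seed, converged=best_success,
                     restart_log=tuple(log))
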