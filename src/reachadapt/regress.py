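"""Statistical modelling of group-averaged behaviour.

Ordinary least-squares regressions on the group-averaged adaptation-phase
series, with sensory uncertainty entered as an ordinal factor under
backward-difference coding (each contrast estimates the difference between
adjacent uncertainty levels).  Three response variables are supported:

* ``imv`` — initial movement vector, predicted by the previous trial's
  uncertainty contrasts, the previous trial's midpoint (and, when endpoint
  feedback exists, endpoint) error, their interactions, and the natural log
  of trial number (which straightens the adaptation curve);
* ``delta_imv`` — trial-to-trial change in IMV, same lagged predictors but
  no trial term;
* ``fb_integration`` — endpoint hand angle minus IMV, predicted by the
  *current* trial's midpoint uncertainty, midpoint error and interaction.

Relative importance of each regressor is the LMG decomposition: the average
over all predictor orderings of the sequential R^2 contribution, which is
non-negative and sums to the model R^2.  The washout analysis compares mean
IMV on the last 10 adaptation trials (grouped by the previous trial's
uncertainty type) with the first 3 washout trials, via repeated-measures
ANOVA and Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm

__all__ = [
    "ContrastScheme",
    "backward_difference_matrix",
    "RegressionSpec",
    "regression_spec_for",
    "build_design",
    "RegressionResult",
    "fit_regression",
    "relative_importance",
    "regression_report",
    "WashoutAnalysis",
    "washout_difference_analysis",
]

MP_LEVEL_ORDER = ["L", "M", "H", "INF"]
COMBO_ORDER = ["LL", "LH", "HL", "HH"]


@dataclass(frozen=True)
class ContrastScheme:
    """Backward-difference coding of an ordered factor."""

    levels: tuple
    matrix: np.ndarray  # (k, k-1): row per level, column per contrast

    def column_names(self, prefix: str = "sigma") -> list:
        return [f"{prefix}[{b}-{a}]"
                for a, b in zip(self.levels[:-1], self.levels[1:])]


def backward_difference_matrix(n_levels: int,
                               levels: Optional[Sequence[str]] = None) -> ContrastScheme:
    """Coding matrix whose fitted coefficients equal adjacent-level mean
    differences on balanced one-way data; columns are centred."""
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if levels is None:
        levels = [str(i) for i in range(n_levels)]
    if len(levels) != n_levels:
        raise ValueError("levels must match n_levels")
    k = n_levels
    mat = np.zeros((k, k - 1))
    for j in range(1, k):
        mat[:j, j - 1] = -(k - j) / k
        mat[j:, j - 1] = j / k
    return ContrastScheme(tuple(levels), mat)


@dataclass(frozen=True)
class RegressionSpec:
    """Which response and predictor set to assemble."""

    response: str                # {"imv", "delta_imv", "fb_integration"}
    uncertainty: str = "mp"      # {"mp", "combo"}
    include_endpoint_error: bool = False

    def __post_init__(self):
        if self.response not in ("imv", "delta_imv", "fb_integration"):
            raise ValueError(f"unknown response: {self.response!r}")
        if self.uncertainty not in ("mp", "combo"):
            raise ValueError(f"unknown uncertainty coding: {self.uncertainty!r}")

    @property
    def lagged(self) -> bool:
        """Feedforward responses use previous-trial predictors."""
        return self.response in ("imv", "delta_imv")

    @property
    def include_log_trial(self) -> bool:
        return self.response == "imv"


def regression_spec_for(experiment_id: int, response: str) -> RegressionSpec:
    """The predictor set each experiment's design supports.

    Experiment 1 has no endpoint feedback, so endpoint-error terms are
    omitted; Experiment 3 codes the four midpoint-by-endpoint combinations
    for the feedforward responses and the two midpoint levels for feedback
    integration.
    """
    if experiment_id not in (1, 2, 3):
        raise ValueError(f"unknown experiment_id: {experiment_id!r}")
    if response == "fb_integration":
        return RegressionSpec(response, uncertainty="mp",
                              include_endpoint_error=False)
    if experiment_id == 1:
        return RegressionSpec(response, "mp", include_endpoint_error=False)
    if experiment_id == 2:
        return RegressionSpec(response, "mp", include_endpoint_error=True)
    return RegressionSpec(response, "combo", include_endpoint_error=True)


def _trial_labels(adapt: pd.DataFrame, coding: str) -> pd.Series:
    if coding == "combo":
        return adapt["mp_uncertainty"].astype(str) + adapt["ep_uncertainty"].astype(str)
    return adapt["mp_uncertainty"].astype(str)


def _level_order(labels: pd.Series, coding: str) -> list:
    order = COMBO_ORDER if coding == "combo" else MP_LEVEL_ORDER
    present = [lvl for lvl in order if lvl in set(labels)]
    missing = set(labels) - set(order)
    if missing:
        raise ValueError(f"unknown uncertainty labels: {sorted(missing)}")
    return present


def build_design(frame: pd.DataFrame, spec: RegressionSpec):
    """Design matrix and response from a group-averaged per-trial table.

    Expects the tabular dialect of :func:`~reachadapt.synth.cohort_group_average`
    (columns trial, phase, rotation_deg, mp_uncertainty, ep_uncertainty,
    imv, mp_angle, ep_angle).  Only adaptation-phase rows enter; lagged
    specs lose the first adaptation trial (undefined lag).
    """
    adapt = frame.loc[frame["phase"] == "adaptation"].reset_index(drop=True)
    if adapt.empty:
        raise ValueError("no adaptation-phase rows")
    labels = _trial_labels(adapt, spec.uncertainty)
    levels = _level_order(labels, spec.uncertainty)
    scheme = backward_difference_matrix(len(levels), levels)
    codes = pd.Series([levels.index(l) for l in labels])
    contrast_cols = scheme.matrix[codes.to_numpy()]
    names = scheme.column_names()

    # errors as experienced: the midpoint flash shows the pre-correction
    # cursor (initial movement direction plus rotation); the endpoint flash
    # shows the final cursor error
    d_mp = adapt["imv"] + adapt["rotation_deg"]
    d_ep = adapt["ep_angle"] + adapt["rotation_deg"]
    trial_no = np.arange(1, len(adapt) + 1)

    X = pd.DataFrame({"Intercept": np.ones(len(adapt))})
    for j, name in enumerate(names):
        X[name] = contrast_cols[:, j]
    X["delta_MP"] = d_mp.to_numpy()
    for j, name in enumerate(names):
        X[f"{name}:delta_MP"] = contrast_cols[:, j] * d_mp.to_numpy()
    if spec.include_endpoint_error:
        X["delta_EP"] = d_ep.to_numpy()
        for j, name in enumerate(names):
            X[f"{name}:delta_EP"] = contrast_cols[:, j] * d_ep.to_numpy()

    if spec.response == "fb_integration":
        y = (adapt["ep_angle"] - adapt["imv"]).rename("fb_integration")
        return X, y

    # feedforward responses: predictors from the previous adaptation trial
    X = X.iloc[:-1].reset_index(drop=True)
    if spec.include_log_trial:
        X["log_trial"] = np.log(trial_no[1:])
    if spec.response == "imv":
        y = adapt["imv"].iloc[1:].reset_index(drop=True).rename("imv")
    else:
        y = adapt["imv"].diff().iloc[1:].reset_index(drop=True).rename("delta_imv")
    return X, y


@dataclass(frozen=True)
class RegressionResult:
    table: pd.DataFrame     # per-term coef, se, T, pval, CI bounds
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float
    nobs: int


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_regression(X: pd.DataFrame, y) -> RegressionResult:
    """Ordinary least squares with classical inference."""
    _check_rank(X)
    model = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = model.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "coef": model.params,
        "se": model.bse,
        "T": model.tvalues,
        "pval": model.pvalues,
        "CI[2.5%]": ci.iloc[:, 0] if hasattr(ci, "iloc") else ci[:, 0],
        "CI[97.5%]": ci.iloc[:, 1] if hasattr(ci, "iloc") else ci[:, 1],
    })
    return RegressionResult(table=table, r2=float(model.rsquared),
                            adj_r2=float(model.rsquared_adj),
                            fvalue=float(model.fvalue),
                            f_pvalue=float(model.f_pvalue),
                            df_model=float(model.df_model),
                            df_resid=float(model.df_resid),
                            nobs=int(model.nobs))


def _subset_r2_cache(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R^2 of every predictor subset (intercept-included models)."""
    p = Z.shape[1]
    M = np.column_stack([Z, y]).astype(float)
    M = M - M.mean(axis=0)
    C = M.T @ M
    syy = C[-1, -1]
    r2 = np.zeros(2 ** p)
    for mask in range(1, 2 ** p):
        idx = [j for j in range(p) if mask & (1 << j)]
        css = C[np.ix_(idx, idx)]
        csy = C[idx, -1]
        beta, *_ = np.linalg.lstsq(css, csy, rcond=None)
        r2[mask] = float(beta @ csy) / syy if syy > 0 else 0.0
    return r2


def relative_importance(X: pd.DataFrame, y) -> pd.Series:
    """LMG shares: average sequential R^2 over all predictor orderings.

    The intercept (any constant column) is excluded; shares are
    non-negative and sum to the full-model R^2.  Exactly collinear
    predictors are admissible here (each subset R^2 uses a least-squares
    pseudo-solution) and split their joint contribution symmetrically.
    """
    pred_cols = [c for c in X.columns
                 if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    Z = X[pred_cols].to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    p = len(pred_cols)
    if p > 16:
        raise ValueError("too many predictors for exact LMG enumeration")
    r2 = _subset_r2_cache(Z, yv)
    fact = [math.factorial(i) for i in range(p + 1)]
    shares = np.zeros(p)
    for j in range(p):
        bit = 1 << j
        for mask in range(2 ** p):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[p - s - 1] / fact[p]
            shares[j] += w * (r2[mask | bit] - r2[mask])
    return pd.Series(shares, index=pred_cols, name="relimp")


def regression_report(frame: pd.DataFrame, spec: RegressionSpec):
    """Fit one regression and attach relative importance to its table."""
    X, y = build_design(frame, spec)
    result = fit_regression(X, y)
    relimp = relative_importance(X, y)
    table = result.table.copy()
    table["relimp"] = relimp.reindex(table.index)
    return RegressionResult(table=table, r2=result.r2, adj_r2=result.adj_r2,
                            fvalue=result.fvalue, f_pvalue=result.f_pvalue,
                            df_model=result.df_model,
                            df_resid=result.df_resid, nobs=result.nobs)


# ---------------------------------------------------------------------------
# Adaptation-vs-washout difference scores


@dataclass(frozen=True)
class WashoutAnalysis:
    scores: pd.DataFrame    # long: participant, type, score
    anova: pd.DataFrame     # repeated-measures ANOVA table
    pairwise: pd.DataFrame  # Bonferroni-corrected paired t-tests


def washout_difference_analysis(cohort, n_last: int = 10,
                                n_washout: int = 3) -> WashoutAnalysis:
    """Difference between late-adaptation accuracy (by the previous trial's
    uncertainty type) and early-washout accuracy, per participant.

    Accuracy is the initial movement vector, the quantity whose washout
    decay indexes the underlying adapted state.
    """
    schedule = cohort[0].schedule
    coding = "combo" if schedule.experiment_id == 3 else "mp"
    phases = np.array([t.phase for t in schedule])
    adapt_pos = np.flatnonzero(phases == "adaptation")
    wash_pos = np.flatnonzero(phases == "washout")
    if adapt_pos.size < n_last or wash_pos.size < n_washout:
        raise ValueError("insufficient adaptation or washout trials")
    last = adapt_pos[-n_last:]
    prev_labels = []
    for i in last:
        t = schedule[i - 1]
        if coding == "combo":
            prev_labels.append(f"{t.mp_uncertainty.label}{t.ep_uncertainty.label}")
        else:
            prev_labels.append(t.mp_uncertainty.label)
    prev_labels = np.array(prev_labels)
    wash_first = wash_pos[:n_washout]
    order = COMBO_ORDER if coding == "combo" else MP_LEVEL_ORDER
    types = [lvl for lvl in order if lvl in set(prev_labels)]

    rows = []
    for ds in cohort:
        wash_mean = float(np.mean(ds.imv[wash_first]))
        for lvl in types:
            sel = last[prev_labels == lvl]
            rows.append({"participant": ds.participant_id, "type": lvl,
                         "score": float(np.mean(ds.imv[sel])) - wash_mean})
    scores = pd.DataFrame(rows)
    anova = pg.rm_anova(data=scores, dv="score", within="type",
                        subject="participant", effsize="ng2")
    pairwise = pg.pairwise_tests(data=scores, dv="score", within="type",
                                 subject="participant", padjust="bonf",
                                 effsize="hedges")
    return WashoutAnalysis(scores, anova, pairwise)
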