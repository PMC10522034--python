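"""Model comparison: BIC scores, per-participant ranks, paired tests.

The criterion is BIC = n*ln(1 - R^2) + k*ln(n) with n the number of fitted
data points, k the number of free parameters and R^2 the variance explained
by the optimised model; lower is preferred.  Within each participant,
models are ranked by ascending BIC (ties broken by fewer parameters, then
by model name, and flagged); cohort-level comparisons are Bonferroni-
corrected paired t-tests with Hedges g effect sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "PerfectFitError",
    "bic",
    "ComparisonTable",
    "rank_models",
    "paired_bic_tests",
]


class PerfectFitError(ValueError):
    """R^2 >= 1 degenerates the criterion (ln of a non-positive number)."""


def bic(n: int, k: int, r2: float) -> float:
    """Bayesian Information Criterion n*ln(1-R^2) + k*ln(n); lower wins.

    ``r2`` may be negative (a model worse than the pooled mean); it must be
    strictly below 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if r2 >= 1.0:
        raise PerfectFitError("R^2 >= 1: residual variance is zero")
    return n * math.log(1.0 - r2) + k * math.log(n)


@dataclass(frozen=True)
class ComparisonTable:
    """Per-participant ranks plus cohort summaries of a model grid."""

    rows: pd.DataFrame          # participant, model, bic, k, rank, tied
    summary: pd.DataFrame       # per-model mean and SD of BIC
    rank_counts: pd.DataFrame   # model x rank histogram
    has_ties: bool


def _bic_and_k(entry) -> tuple:
    if hasattr(entry, "bic"):
        return float(entry.bic), int(getattr(entry, "k", 0))
    return float(entry), 0


def rank_models(fits: Mapping[str, Mapping[str, object]]) -> ComparisonTable:
    """Rank every model within every participant by ascending BIC.

    ``fits`` maps participant id -> model name -> FitResult (or a bare BIC
    value).  Every participant must carry a fit for every model.
    """
    participants = list(fits)
    if not participants:
        raise ValueError("no fits supplied")
    models = sorted(fits[participants[0]])
    for p in participants:
        if sorted(fits[p]) != models:
            raise ValueError(f"incomplete model grid for participant {p!r}")

    rows = []
    has_ties = False
    for p in participants:
        entries = []
        for m in models:
            b, k = _bic_and_k(fits[p][m])
            entries.append((b, k, m))
        # ties broken by fewer parameters, then lexicographic model name
        order = sorted(entries)
        bics = [e[0] for e in entries]
        tied_values = {b for b in bics if bics.count(b) > 1}
        has_ties = has_ties or bool(tied_values)
        for rank, (b, k, m) in enumerate(order, start=1):
            rows.append({"participant": p, "model": m, "bic": b, "k": k,
                         "rank": rank, "tied": b in tied_values})
    rows = pd.DataFrame(rows)
    summary = (rows.groupby("model")["bic"]
               .agg(["mean", "std"]).reset_index())
    rank_counts = (rows.pivot_table(index="model", columns="rank",
                                    values="participant", aggfunc="count",
                                    fill_value=0))
    return ComparisonTable(rows, summary, rank_counts, has_ties)


def _paired_t_record(a: np.ndarray, b: np.ndarray, label_a: str,
                     label_b: str, n_comparisons: int) -> dict:
    diffs = a - b
    if np.all(diffs == 0):
        # degenerate case: identical paired vectors
        return {"A": label_a, "B": label_b, "T": 0.0,
                "dof": float(len(a) - 1), "p_corr": 1.0, "hedges": 0.0,
                "mean_A": float(np.mean(a)), "mean_B": float(np.mean(b))}
    tt = pg.ttest(a, b, paired=True)
    g = pg.compute_effsize(a, b, paired=True, eftype="hedges")
    pcol = "p_val" if "p_val" in tt.columns else "p-val"
    p = float(tt[pcol].iloc[0])
    return {
        "A": label_a, "B": label_b,
        "T": float(tt["T"].iloc[0]),
        "dof": float(tt["dof"].iloc[0]),
        "p_corr": min(1.0, p * n_comparisons),
        "hedges": float(g),
        "mean_A": float(np.mean(a)), "mean_B": float(np.mean(b)),
    }


def paired_bic_tests(fits: Mapping[str, Mapping[str, object]],
                     grouping: str = "by_states") -> pd.DataFrame:
    """Cohort-level paired t-tests on BIC, Bonferroni corrected.

    ``by_states`` compares each participant's mean BIC over two-state
    variants against one-state variants (one test).  ``by_family`` runs all
    pairwise comparisons between scaling families on per-participant mean
    BIC within family.  Model names must follow ``family-...state...`` as
    produced by :class:`~reachadapt.models.ModelSpec`.
    """
    participants = list(fits)
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for paired tests")
    models = sorted(fits[participants[0]])

    def mean_bic(p, selector) -> float:
        vals = [_bic_and_k(fits[p][m])[0] for m in models if selector(m)]
        if not vals:
            raise ValueError("grouping selects no models")
        return float(np.mean(vals))

    if grouping == "by_states":
        two = np.array([mean_bic(p, lambda m: "-2state" in m)
                        for p in participants])
        one = np.array([mean_bic(p, lambda m: "-1state" in m)
                        for p in participants])
        return pd.DataFrame([_paired_t_record(two, one, "two-state",
                                              "one-state", 1)])
    if grouping == "by_family":
        families = sorted({m.split("-")[0] for m in models})
        pairs = list(itertools.combinations(families, 2))
        records = []
        for fa, fb in pairs:
            a = np.array([mean_bic(p, lambda m: m.split("-")[0] == fa)
                          for p in participants])
            b = np.array([mean_bic(p, lambda m: m.split("-")[0] == fb)
                          for p in participants])
            records.append(_paired_t_record(a, b, fa, fb, len(pairs)))
        return pd.DataFrame(records)
    raise ValueError(f"unknown grouping: {grouping!r}")
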