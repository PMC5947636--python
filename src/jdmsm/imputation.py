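"""Multiple imputation of missing PGA and CMAS values.

Chained equations with normal linear conditional models and proper
(Bayesian) parameter draws: for each imputed set, each incomplete score is
regressed on the complete skin score, the other incomplete score (current
completion), time since diagnosis, treatment state, treatment recency and
age at diagnosis; the residual variance and coefficients are drawn from
their posterior before imputing, so the m sets carry genuine
between-imputation variability.  Draws outside a score's range are clipped.

Treatment recency (the split-time category) is included among the
predictors so the imputation model is congenial with the final analytical
model: omitting the analysis model's treatment covariate would attenuate
or distort treatment effects in the imputed cells.

All downstream stages of the pipeline run once per imputed set, with
estimates pooled at the very end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import SCORE_RANGES, SPLIT_TIME_ORDER, CohortTable, split_time_categories
from .errors import InsufficientDataError, ValidationError

__all__ = ["ImputedSet", "impute", "across_sets"]

DEFAULT_VARIABLES = ("pga", "cmas")
_RANGES = {**SCORE_RANGES, "gc_dose": (0.0, None)}


@dataclass
class ImputedSet:
    """One completed copy of the cohort plus the mask of originally-missing
    cells (visit-row aligned, one boolean column per imputed variable)."""

    index: int
    cohort: CohortTable
    mask: pd.DataFrame


def _predictor_matrix(frame: pd.DataFrame, target: str, variables: Sequence[str]) -> np.ndarray:
    cols = [frame["das"].to_numpy(dtype=float)]
    for other in variables:
        if other != target:
            cols.append(frame[other].to_numpy(dtype=float))
    cols.append(frame["t"].to_numpy(dtype=float))
    cols.append(frame["on_cyc"].to_numpy(dtype=float))
    cats = split_time_categories(frame["t"], frame["cyc_start"])
    for cat in SPLIT_TIME_ORDER[1:]:
        cols.append((np.asarray(cats) == cat.value).astype(float))
    cols.append(frame["age_at_diagnosis"].to_numpy(dtype=float))
    # first-visit skin score: a persistent-severity summary of the patient's
    # history that the current-visit predictors alone do not carry
    cols.append(frame["baseline_das"].to_numpy(dtype=float))
    # longitudinal structure: the patient's nearest observed earlier/later
    # value of the target score (scores are strongly autocorrelated between
    # adjacent visits, so these sharpen the imputed cells considerably)
    for side in ("prev", "next"):
        cols.append(frame[f"{target}_{side}_obs"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(frame))] + cols)
    return X


def _draw_completion(
    X: np.ndarray, y: np.ndarray, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-draw linear imputation of y[miss] given X (proper MI)."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    beta_hat, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(len(yo) - rank, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    XtX = Xo.T @ Xo
    # ridge jitter guards against exactly collinear predictors
    cov = np.linalg.pinv(XtX + 1e-8 * np.eye(XtX.shape[0])) * sigma2
    beta = rng.multivariate_normal(beta_hat, (cov + cov.T) / 2.0)
    return X[miss] @ beta + np.sqrt(sigma2) * rng.standard_normal(int(miss.sum()))


def impute(
    cohort: CohortTable,
    m: int = 5,
    seed: int = 0,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    n_sweeps: int = 5,
) -> list[ImputedSet]:
    """Produce ``m`` stochastic completions of the cohort's visit table.

    Missingness must be confined to ``variables`` (by default PGA and CMAS;
    gc_dose may be added) with the skin score complete.  A fixed seed gives
    bit-identical sets; originally-observed cells are never altered.
    """
    if m < 1:
        raise ValidationError("m must be at least 1")
    if cohort.visits["das"].isna().any():
        raise ValidationError("the skin DAS must be complete before imputation")
    merged = cohort.merged()
    merged["baseline_das"] = merged.groupby("patient_id")["das"].transform("first")
    for v in variables:
        if v in merged.columns:
            g = merged.groupby("patient_id")[v]
            prev_obs = g.transform(lambda x: x.shift(1).ffill())
            next_obs = g.transform(lambda x: x.shift(-1).bfill())
            pmean = g.transform("mean")
            fallback = pmean.fillna(merged[v].mean())
            merged[f"{v}_prev_obs"] = prev_obs.fillna(fallback)
            merged[f"{v}_next_obs"] = next_obs.fillna(fallback)
    mask = pd.DataFrame(
        {v: cohort.visits[v].isna().to_numpy() for v in variables},
        index=cohort.visits.index,
    )
    for v in variables:
        if v not in cohort.visits.columns:
            raise ValidationError(f"unknown imputation variable '{v}'")
        if mask[v].all():
            raise InsufficientDataError(
                f"'{v}' is missing for every visit; its imputation model is inestimable"
            )
    # gc_dose may stay missing: it is excluded from imputation and from the
    # analytical models by default (heavy, possibly informative missingness)
    other = [
        c for c in ("pga", "cmas") if c not in variables and cohort.visits[c].isna().any()
    ]
    if other:
        raise ValidationError(
            f"missing values outside the imputation variables: {other}; "
            "add them to `variables` or complete them first"
        )
    children = np.random.SeedSequence(seed).spawn(m)
    sets = []
    for j in range(m):
        rng = np.random.default_rng(children[j])
        work = merged.copy()
        # deterministic warm start: observed means
        for v in variables:
            work.loc[mask[v].to_numpy(), v] = work[v].mean()
        n_sw = n_sweeps if any(mask[v].any() for v in variables) else 0
        for _ in range(n_sw):
            for v in variables:
                miss = mask[v].to_numpy()
                if not miss.any():
                    continue
                X = _predictor_matrix(work, v, variables)
                draws = _draw_completion(X, work[v].to_numpy(dtype=float), miss, rng)
                lo, hi = _RANGES[v]
                work.loc[miss, v] = np.clip(draws, lo, np.inf if hi is None else hi)
        visits = cohort.visits.copy()
        for v in variables:
            visits[v] = work[v].to_numpy(dtype=float)
        sets.append(ImputedSet(j + 1, CohortTable(cohort.patients.copy(), visits), mask.copy()))
    return sets


def across_sets(sets: Sequence[ImputedSet], stage: Callable[[ImputedSet], object]) -> list:
    """Apply a pipeline stage independently to each imputed set, preserving
    order.  A failure on any set aborts the whole run (pooling over a
    subset of imputations would bias the combined variance)."""
    out = []
    for s in sets:
        try:
            out.append(stage(s))
        except Exception as err:
            raise RuntimeError(f"pipeline stage failed on imputed set {s.index}") from err
    return out
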