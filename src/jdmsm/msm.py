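"""Weighted longitudinal outcome models, Rubin pooling and the end-to-end
marginal-structural-model (MSM) pipeline.

The final analytical model regresses each disease-activity score on time
since diagnosis and the treatment-recency ("split time") category, fitted
by weighted estimating equations with an independence working correlation
and a cluster-by-patient robust (sandwich) variance that incorporates the
inverse-probability-of-treatment weights.  With an identity link and
independence working correlation the point estimates coincide with
weighted least squares, which is how they are computed; the sandwich
variance is the standard cluster-robust one evaluated at those weights.

Per-imputation estimates are combined with Rubin's rules (total variance =
within + (1 + 1/m) x between) using Barnard-Rubin small-sample degrees of
freedom for the t reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .cohort import (
    TREATED_CATEGORIES,
    CohortTable,
    SplitTime,
    apply_eligibility,
    split_time_categories,
)
from .errors import ValidationError
from .imputation import impute
from .potm import fit_potm, predict_treatment_probabilities, treatment_frame
from .weights import DEFAULT_CAP, WeightSeries, compute_weights

__all__ = [
    "EffectEstimate",
    "PooledEffect",
    "OutcomeFit",
    "MsmConfig",
    "MsmResult",
    "fit_weighted_outcome",
    "pool_rubin",
    "pool_scalar",
    "run_msm",
    "forest_table",
    "format_forest",
]

OUTCOMES = ("das", "pga", "cmas")


@dataclass
class EffectEstimate:
    """One split-time coefficient from one analytical model fit (reference
    category: never/not yet treated)."""

    outcome: str
    category: SplitTime
    coefficient: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    set_index: int | None = None
    estimable: bool = True


@dataclass
class OutcomeFit:
    outcome: str
    estimates: list
    params: pd.Series
    n_obs: int
    n_patients: int
    set_index: int | None = None


@dataclass
class PooledEffect:
    """Rubin-combined coefficient for one (outcome, split-time category)."""

    outcome: str
    category: SplitTime
    coefficient: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int
    estimable: bool = True


def _design_matrix(frame: pd.DataFrame, time_covariate: bool = True):
    cats = split_time_categories(frame["t"], frame["cyc_start"])
    cols, names = [np.ones(len(frame))], ["const"]
    if time_covariate:
        cols.append(frame["t"].to_numpy(dtype=float))
        names.append("t")
    present = []
    arr = np.asarray(cats)
    for cat in TREATED_CATEGORIES:
        ind = (arr == cat.value).astype(float)
        if ind.any():
            cols.append(ind)
            names.append(cat.value)
            present.append(cat)
    return np.column_stack(cols), names, present


def fit_weighted_outcome(
    cohort: CohortTable,
    weights: WeightSeries | None = None,
    outcome: str = "das",
    time_covariate: bool = True,
    set_index: int | None = None,
) -> OutcomeFit:
    """Fit one outcome's weighted analytical model.

    ``weights=None`` fits the unweighted (naive) comparator.  Rows with a
    missing outcome are dropped (after imputation there are none).  A
    split-time category with no observed visits is reported as inestimable
    rather than silently omitted.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome '{outcome}'")
    merged = cohort.merged()
    if weights is None:
        w = np.ones(len(merged))
    else:
        if len(weights.table) != len(merged) or not np.allclose(
            weights.table["t"].to_numpy(), merged["t"].to_numpy()
        ):
            raise ValidationError("weights are not aligned with the cohort's visits")
        w = weights.table["truncated"].to_numpy(dtype=float)
    keep = merged[outcome].notna().to_numpy()
    frame = merged[keep]
    w = w[keep]
    y = frame[outcome].to_numpy(dtype=float)
    X, names, present = _design_matrix(frame, time_covariate)
    groups = frame["patient_id"].to_numpy()
    res = sm.WLS(y, X, weights=w).fit(
        cov_type="cluster", cov_kwds={"groups": groups}, use_t=True
    )
    params = pd.Series(res.params, index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    n_pat = len(np.unique(groups))
    df_com = max(n_pat - len(names), 1)
    tcrit = stats.t.ppf(0.975, df_com)
    estimates = []
    for cat in TREATED_CATEGORIES:
        if cat not in present:
            estimates.append(
                EffectEstimate(outcome, cat, np.nan, np.nan, np.nan, np.nan, np.nan,
                               df_com, set_index, estimable=False)
            )
            continue
        b, se = params[cat.value], bse[cat.value]
        p = 2 * stats.t.sf(abs(b / se), df_com)
        estimates.append(
            EffectEstimate(outcome, cat, float(b), float(se), float(b - tcrit * se),
                           float(b + tcrit * se), float(p), float(df_com), set_index)
        )
    return OutcomeFit(outcome, estimates, params, len(frame), n_pat, set_index)


def pool_scalar(coefs, variances, df_com: float) -> dict:
    """Rubin's rules for one scalar across m imputations.

    Returns pooled estimate, within/between/total variance, Barnard-Rubin
    degrees of freedom, 95% CI and two-sided p from the t reference.
    """
    q = np.asarray(coefs, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValidationError("pooling requires at least 2 imputations")
    qbar = q.mean()
    w_var = u.mean()
    b_var = q.var(ddof=1)
    t_var = w_var + (1 + 1 / m) * b_var
    if b_var == 0:
        df = float(df_com)
    else:
        gamma = (1 + 1 / m) * b_var / t_var
        nu_old = (m - 1) / gamma**2
        nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - gamma)
        df = float(nu_old * nu_obs / (nu_old + nu_obs))
    se = np.sqrt(t_var)
    tcrit = stats.t.ppf(0.975, df)
    p = float(2 * stats.t.sf(abs(qbar / se), df)) if se > 0 else (0.0 if qbar else 1.0)
    return dict(
        coefficient=float(qbar), within_variance=float(w_var), between_variance=float(b_var),
        total_variance=float(t_var), robust_se=float(se), df=df,
        ci_low=float(qbar - tcrit * se), ci_high=float(qbar + tcrit * se), p_value=p, m=m,
    )


def pool_rubin(per_set_fits) -> list[PooledEffect]:
    """Combine per-imputation :class:`OutcomeFit` objects (same outcome)
    into one :class:`PooledEffect` per split-time category."""
    fits = list(per_set_fits)
    if len(fits) < 2:
        raise ValidationError("pooling requires at least 2 imputed-set fits")
    outcome = fits[0].outcome
    by_cat = {}
    for f in fits:
        if f.outcome != outcome:
            raise ValidationError("cannot pool fits of different outcomes")
        cats = tuple((e.category, e.estimable) for e in f.estimates)
        by_cat.setdefault("sig", cats)
        if cats != by_cat["sig"]:
            raise ValidationError("imputed sets disagree on estimable categories")
    pooled = []
    for i, cat in enumerate(TREATED_CATEGORIES):
        ests = [f.estimates[i] for f in fits]
        if not ests[0].estimable:
            pooled.append(
                PooledEffect(outcome, cat, np.nan, np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan, np.nan, np.nan, len(fits), estimable=False)
            )
            continue
        res = pool_scalar(
            [e.coefficient for e in ests],
            [e.robust_se**2 for e in ests],
            df_com=float(np.min([e.df for e in ests])),
        )
        pooled.append(PooledEffect(outcome=outcome, category=cat, **res))
    return pooled


@dataclass
class MsmConfig:
    """Settings for the full pipeline run."""

    m: int = 5
    seed: int = 0
    cap: float = DEFAULT_CAP
    stabilized: bool = True
    outcomes: tuple = OUTCOMES
    eligibility: bool = True
    time_covariate: bool = True
    impute_variables: tuple = ("pga", "cmas")


@dataclass
class MsmResult:
    pooled: dict  # outcome -> list[PooledEffect]
    per_set: dict  # outcome -> list[OutcomeFit]
    weights: list  # WeightSeries per imputed set
    exclusions: pd.DataFrame | None
    logs: list = field(default_factory=list)

    def pooled_effect(self, outcome: str, category: SplitTime) -> PooledEffect:
        for e in self.pooled[outcome]:
            if e.category == category:
                return e
        raise KeyError((outcome, category))


def run_msm(cohort: CohortTable, config: MsmConfig | None = None) -> MsmResult:
    """Run the whole MSM pipeline on a cohort.

    Stages: eligibility filter -> multiple imputation (m sets) -> per-set
    probability-of-treatment models (denominator and stabilization
    numerator) -> per-set stabilized, truncated weights -> per-set weighted
    outcome models -> Rubin pooling.  Weights are recomputed for every
    imputed set, since each set has its own PoTM.
    """
    cfg = config or MsmConfig()
    logs = []
    exclusions = None
    if cfg.eligibility:
        cohort, exclusions = apply_eligibility(cohort)
        logs.append(f"eligibility: retained {cohort.n_patients}, excluded {len(exclusions)}")
    anybody_treated = cohort.patients["cyc_start"].notna().any()
    sets = impute(cohort, m=cfg.m, seed=cfg.seed, variables=list(cfg.impute_variables))
    logs.append(f"imputation: {cfg.m} sets, variables {list(cfg.impute_variables)}")
    weight_series = []
    per_set = {o: [] for o in cfg.outcomes}
    for s in sets:
        frame = treatment_frame(s.cohort)
        if anybody_treated:
            den = fit_potm(frame, numerator=False)
            p_den = predict_treatment_probabilities(den, frame)
            if cfg.stabilized:
                num = fit_potm(frame, numerator=True)
                p_num = predict_treatment_probabilities(num, frame)
            else:
                p_num = None
            ws = compute_weights(p_den, p_num, cap=cfg.cap)
        else:
            table = frame[["patient_id", "t"]].copy()
            table["raw"] = 1.0
            table["truncated"] = 1.0
            ws = WeightSeries(table, cfg.cap, cfg.stabilized)
            logs.append(f"set {s.index}: nobody treated; weights identically 1")
        weight_series.append(ws)
        for outcome in cfg.outcomes:
            per_set[outcome].append(
                fit_weighted_outcome(
                    s.cohort, ws, outcome, time_covariate=cfg.time_covariate,
                    set_index=s.index,
                )
            )
        logs.append(
            f"set {s.index}: mean raw weight {ws.raw.mean():.3f}, "
            f"{ws.n_truncated} truncated at {cfg.cap:g}"
        )
    pooled = {o: pool_rubin(per_set[o]) for o in cfg.outcomes}
    return MsmResult(pooled, per_set, weight_series, exclusions, logs)


def forest_table(pooled: dict) -> pd.DataFrame:
    """Tabular forest-plot layout: one row per (outcome, category) with the
    pooled coefficient, 95% CI, p-value and a significance marker."""
    rows = []
    for outcome, effects in pooled.items():
        for e in effects:
            rows.append(
                dict(outcome=outcome, category=e.category.value,
                     coefficient=e.coefficient, ci_low=e.ci_low, ci_high=e.ci_high,
                     p_value=e.p_value, significant=bool(e.estimable and e.p_value < 0.05),
                     estimable=e.estimable)
            )
    return pd.DataFrame(rows)


def format_forest(table: pd.DataFrame) -> str:
    """Plain-text rendering; inestimable entries print as dashes."""
    lines = [f"{'outcome':8s} {'category':14s} {'coef':>8s} {'95% CI':>20s} {'p':>9s}"]
    for _, r in table.iterrows():
        if not r["estimable"]:
            lines.append(f"{r['outcome']:8s} {r['category']:14s} {'—':>8s} {'—':>20s} {'—':>9s}")
            continue
        ci = f"[{r['ci_low']:7.2f}, {r['ci_high']:6.2f}]"
        star = " *" if r["significant"] else ""
        lines.append(
            f"{r['outcome']:8s} {r['category']:14s} {r['coefficient']:8.2f} {ci:>20s} "
            f"{r['p_value']:9.4f}{star}"
        )
    return "\n".join(lines)
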