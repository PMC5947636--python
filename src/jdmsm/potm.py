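"""Probability-of-treatment model (PoTM): three discrete-time sub-models
whose per-visit predictions form inverse-probability-of-treatment weights.

Treatment state changes are modelled on the visit grid (a discrete-time
hazard formulation — registries record treatment at clinic visits):

1. *baseline receipt* — probability of being on CYC at the first recorded
   visit, a logistic model over patients;
2. *initiation* — probability that an as-yet-untreated patient starts CYC
   at a given visit, a pooled longitudinal logistic model with
   cluster-robust (by patient) standard errors;
3. *discontinuation* — probability that a patient on CYC is off treatment
   by the next visit.  Because the treatment course is protocolized
   (~5-6 months, no discontinuers), time-on-treatment predicts stopping
   almost deterministically; on quasi-separation the model falls back to a
   coarse time-banded empirical hazard with add-half smoothing, which keeps
   every probability strictly inside (0, 1).

Denominator models condition on current disease-activity scores and
concomitant-medication flags (the time-varying confounders); numerator
models for weight stabilization use baseline covariates (age, sex) plus
time since diagnosis only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

import statsmodels.api as sm

from .cohort import CohortTable
from .errors import (
    InsufficientDataError,
    PositivityError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "PropensityFit",
    "PotmFits",
    "DENOMINATOR_COVARIATES",
    "NUMERATOR_COVARIATES",
    "treatment_frame",
    "fit_baseline_model",
    "fit_initiation_model",
    "fit_discontinuation_model",
    "fit_potm",
    "predict_treatment_probabilities",
]

DENOMINATOR_COVARIATES = {
    "baseline": ["das", "pga", "cmas", "age_at_diagnosis"],
    "initiation": ["das", "pga", "cmas", "t", "age_at_diagnosis", "iv_gc", "ivig", "biologic"],
    "discontinuation": ["time_on_cyc"],
}
# Stabilization numerators may only condition on covariates the final
# analytical model also adjusts for (otherwise the pseudo-population is
# balanced only conditionally and residual confounding leaks into the
# marginal estimate).  The final model adjusts for time since diagnosis and
# treatment recency, so the numerators use time since diagnosis and (for
# stopping) time on treatment — the latter is a function of treatment
# history, not a confounder, and with identical numerator and denominator
# stop structures the protocolized stop factors cancel instead of adding
# weight variance.
NUMERATOR_COVARIATES = {
    "baseline": [],
    "initiation": ["t"],
    "discontinuation": ["time_on_cyc"],
}

_STOP_BANDS = (0.0, 3.0, 4.5, 6.0, 9.0, np.inf)
_MAX_ABS_COEF = 15.0  # larger fitted log-odds indicate (quasi-)separation


@dataclass
class PropensityFit:
    """A fitted PoTM sub-model with per-visit predictions.

    Either a logistic fit (``params``/``robust_se`` populated) or, for the
    discontinuation fallback, a banded empirical hazard (``band_edges`` /
    ``band_probs``).  ``fitted`` holds predictions for the sub-model's risk
    set, indexed like the risk-set rows.
    """

    submodel: str
    params: pd.Series | None
    robust_se: pd.Series | None
    fitted: pd.Series
    converged: bool
    n: int
    fallback: bool = False
    dropped: list = field(default_factory=list)
    band_edges: tuple | None = None
    band_probs: np.ndarray | None = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        if self.fallback:
            idx = np.digitize(frame["time_on_cyc"].to_numpy(dtype=float), self.band_edges) - 1
            idx = np.clip(idx, 0, len(self.band_probs) - 1)
            return self.band_probs[idx]
        X = _design(frame, [c for c in self.params.index if c != "const"])
        return expit(X @ self.params.to_numpy())


@dataclass
class PotmFits:
    baseline: PropensityFit
    initiation: PropensityFit
    discontinuation: PropensityFit | None  # None when nobody is ever treated


def treatment_frame(cohort: CohortTable) -> pd.DataFrame:
    """Visit table joined with patient covariates plus the derived columns
    the sub-models need: visit rank, treatment-state indicators for the
    current and previous visit, and time on treatment."""
    m = cohort.merged().copy()
    m["sex_female"] = (m["sex"] == "female").astype(float)
    m["visit_rank"] = m.groupby("patient_id").cumcount()
    started = (m["t"] >= m["cyc_start"]).fillna(False)
    m["started"] = started.to_numpy(dtype=bool)
    g = m.groupby("patient_id")
    m["prev_started"] = g["started"].shift(1, fill_value=False).to_numpy(dtype=bool)
    m["prev_on"] = g["on_cyc"].shift(1, fill_value=False).to_numpy(dtype=bool)
    m["time_on_cyc"] = np.where(m["started"], m["t"] - m["cyc_start"], np.nan)
    for flag in ("iv_gc", "ivig", "biologic"):
        m[flag] = m[flag].astype(float)
    m["on_cyc"] = m["on_cyc"].astype(bool)
    return m


def _design(frame: pd.DataFrame, covariates) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
    )
    return X


def _fit_logistic(
    y: np.ndarray,
    frame: pd.DataFrame,
    covariates,
    submodel: str,
    groups=None,
    penalty: float = 0.0,
):
    """Logistic fit with zero-variance covariates dropped, optional ridge
    penalty, and separation detection."""
    kept, dropped = [], []
    for c in covariates:
        x = frame[c].to_numpy(dtype=float)
        (kept if np.nanstd(x) > 1e-12 else dropped).append(c)
    X = _design(frame, kept)
    names = ["const"] + kept
    if penalty > 0:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit_regularized(alpha=penalty, L1_wt=0.0)
        params = pd.Series(res.params, index=names)
        fitted = pd.Series(expit(X @ res.params), index=frame.index)
        return params, pd.Series(np.nan, index=names), fitted, True, dropped
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # near-deterministic targets are detected below and either raised as
            # SeparationError or routed to a fallback; the warning is redundant
            warnings.simplefilter("ignore")
            if groups is not None and len(np.unique(groups)) > 1:
                res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
            else:
                res = model.fit(cov_type="HC1")
    except np.linalg.LinAlgError as err:
        raise SeparationError(
            f"{submodel} model could not be fitted (singular information); "
            "the treatment state is (quasi-)separated. Refit with penalty > 0."
        ) from err
    converged = bool(res.converged)
    params = pd.Series(res.params, index=names)
    if (not converged) or np.abs(res.params).max() > _MAX_ABS_COEF:
        worst = names[int(np.abs(params.to_numpy()).argmax())]
        raise SeparationError(
            f"{submodel} model is (quasi-)separated; covariate '{worst}' nearly "
            "perfectly predicts the treatment state. Refit with penalty > 0."
        )
    se = pd.Series(np.asarray(res.bse), index=names)
    fitted = pd.Series(np.asarray(res.predict()), index=frame.index)
    return params, se, fitted, converged, dropped


def fit_baseline_model(
    cohort_or_frame, covariates=None, penalty: float = 0.0
) -> PropensityFit:
    """Probability of being on CYC at the first recorded visit."""
    frame = _as_frame(cohort_or_frame)
    covariates = DENOMINATOR_COVARIATES["baseline"] if covariates is None else covariates
    rows = frame[frame["visit_rank"] == 0]
    y = rows["on_cyc"].to_numpy(dtype=float)
    if len(rows) == 0:
        raise InsufficientDataError("no baseline visits")
    if y.sum() == 0 or y.sum() == len(y):
        # a constant target is common (nobody on CYC at the very first visit);
        # fall back to a smoothed empirical fraction so weights stay defined
        p = (y.sum() + 0.5) / (len(y) + 1.0)
        return PropensityFit(
            "baseline", pd.Series({"const": float(np.log(p / (1 - p)))}), None,
            pd.Series(np.full(len(rows), p), index=rows.index),
            converged=True, n=len(rows), fallback=False, dropped=list(covariates),
        )
    params, se, fitted, conv, dropped = _fit_logistic(
        y, rows, covariates, "baseline receipt", penalty=penalty
    )
    return PropensityFit("baseline", params, se, fitted, conv, len(rows), dropped=dropped)


def fit_initiation_model(
    cohort_or_frame, covariates=None, penalty: float = 0.0
) -> PropensityFit:
    """Discrete-time hazard of starting CYC at a visit, among visits of
    patients not previously treated (the first visit belongs to the
    baseline-receipt model)."""
    frame = _as_frame(cohort_or_frame)
    covariates = DENOMINATOR_COVARIATES["initiation"] if covariates is None else covariates
    rows = frame[(frame["visit_rank"] >= 1) & (~frame["prev_started"])]
    if rows.empty:
        raise InsufficientDataError("initiation risk set is empty")
    y = rows["started"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise InsufficientDataError(
            "nobody initiates CYC after baseline; initiation weights would be trivially 1"
        )
    params, se, fitted, conv, dropped = _fit_logistic(
        y, rows, covariates, "initiation", groups=rows["patient_id"], penalty=penalty
    )
    return PropensityFit("initiation", params, se, fitted, conv, len(rows), dropped=dropped)


def fit_discontinuation_model(cohort_or_frame, covariates=None) -> PropensityFit:
    """Discrete-time hazard of being off CYC at a visit, among visits whose
    previous visit was on treatment.

    Stopping is driven by the protocol course length, so a logistic model in
    time-on-treatment is attempted first and, on quasi-separation, replaced
    by a banded empirical hazard (add-half smoothing per band)."""
    frame = _as_frame(cohort_or_frame)
    covariates = DENOMINATOR_COVARIATES["discontinuation"] if covariates is None else covariates
    rows = frame[(frame["visit_rank"] >= 1) & frame["prev_on"]]
    if rows.empty:
        raise InsufficientDataError("discontinuation risk set is empty (no treated patients)")
    y = (~rows["on_cyc"].to_numpy(dtype=bool)).astype(float)
    try:
        if y.sum() in (0, len(y)):
            raise SeparationError("constant stop target")
        params, se, fitted, conv, dropped = _fit_logistic(
            y, rows, covariates, "discontinuation", groups=rows["patient_id"]
        )
        if fitted.min() < 1e-9 or fitted.max() > 1 - 1e-9:
            raise SeparationError("fitted stop probabilities collapse to 0/1")
        return PropensityFit(
            "discontinuation", params, se, fitted, conv, len(rows), dropped=dropped
        )
    except SeparationError:
        edges = np.asarray(_STOP_BANDS[:-1])
        idx = np.clip(
            np.digitize(rows["time_on_cyc"].to_numpy(dtype=float), edges) - 1,
            0,
            len(edges) - 1,
        )
        probs = np.empty(len(edges))
        for b in range(len(edges)):
            sel = idx == b
            probs[b] = (y[sel].sum() + 0.5) / (sel.sum() + 1.0)
        fitted = pd.Series(probs[idx], index=rows.index)
        return PropensityFit(
            "discontinuation", None, None, fitted, converged=True, n=len(rows),
            fallback=True, band_edges=tuple(edges), band_probs=probs,
        )


def _as_frame(cohort_or_frame) -> pd.DataFrame:
    if isinstance(cohort_or_frame, CohortTable):
        return treatment_frame(cohort_or_frame)
    return cohort_or_frame


def fit_potm(cohort_or_frame, numerator: bool = False, penalty: float = 0.0) -> PotmFits:
    """Fit all three sub-models.

    ``numerator=True`` selects the stabilization covariate sets (baseline
    covariates and time only); otherwise the full denominator sets are
    used.  The baseline sub-model retries with a light ridge penalty on
    separation — its event count is small in early-treatment cohorts.
    """
    frame = _as_frame(cohort_or_frame)
    sets = NUMERATOR_COVARIATES if numerator else DENOMINATOR_COVARIATES
    try:
        base = fit_baseline_model(frame, covariates=sets["baseline"], penalty=penalty)
    except SeparationError:
        base = fit_baseline_model(frame, covariates=sets["baseline"], penalty=1.0 / len(frame))
    try:
        init = fit_initiation_model(frame, covariates=sets["initiation"], penalty=penalty)
    except SeparationError:
        init = fit_initiation_model(
            frame, covariates=sets["initiation"], penalty=1.0 / len(frame)
        )
    any_treated = frame["started"].any()
    disc = (
        fit_discontinuation_model(frame, covariates=sets["discontinuation"])
        if any_treated and ((frame["visit_rank"] >= 1) & frame["prev_on"]).any()
        else None
    )
    return PotmFits(base, init, disc)


def predict_treatment_probabilities(fits: PotmFits, cohort_or_frame) -> pd.DataFrame:
    """Per-visit probability of the treatment state actually observed.

    Visit 1 uses the baseline-receipt model; as long as the patient has not
    started, each visit contributes the initiation hazard (start) or its
    complement (no start); while the previous visit was on treatment, the
    discontinuation hazard (stop) or its complement (continue); once the
    single course is over the history is fixed and the factor is exactly 1.

    Raises :class:`PositivityError` if any sub-model probability reaches 0
    or 1 in floating point.
    """
    frame = _as_frame(cohort_or_frame)
    p = np.ones(len(frame))
    at_base = (frame["visit_rank"] == 0).to_numpy()
    p0 = fits.baseline.predict(frame[at_base])
    _check_positivity(p0, "baseline receipt")
    on0 = frame.loc[at_base, "on_cyc"].to_numpy(dtype=bool)
    p[at_base] = np.where(on0, p0, 1.0 - p0)
    at_risk = ((frame["visit_rank"] >= 1) & (~frame["prev_started"])).to_numpy()
    if at_risk.any():
        h = fits.initiation.predict(frame[at_risk])
        _check_positivity(h, "initiation")
        starts = frame.loc[at_risk, "started"].to_numpy(dtype=bool)
        p[at_risk] = np.where(starts, h, 1.0 - h)
    stopping = ((frame["visit_rank"] >= 1) & frame["prev_on"]).to_numpy()
    if stopping.any():
        if fits.discontinuation is None:
            raise ValidationError("treated visits present but no discontinuation model")
        hs = fits.discontinuation.predict(frame[stopping])
        _check_positivity(hs, "discontinuation")
        off = ~frame.loc[stopping, "on_cyc"].to_numpy(dtype=bool)
        p[stopping] = np.where(off, hs, 1.0 - hs)
    out = frame[["patient_id", "t"]].copy()
    out["p_state"] = p
    return out


def _check_positivity(p: np.ndarray, label: str) -> None:
    if p.size and (p.min() <= 0.0 or p.max() >= 1.0):
        raise PositivityError(
            f"{label} model emitted a probability of 0 or 1; positivity violated"
        )
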