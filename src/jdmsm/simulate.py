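"""Synthetic longitudinal cohorts with confounding by indication.

The generator emulates the statistical structure of a juvenile
dermatomyositis registry in which sicker children are preferentially
started on a short cyclophosphamide (CYC) course shortly after diagnosis:

* a latent severity scalar per patient (on the 0-10 global-assessment
  scale) that declines linearly with time since diagnosis and carries
  mean-reverting visit-to-visit deviations;
* three observed scores that are noisy monotone transforms of severity,
  clipped to their instruments' ranges (skin DAS 0-5 and PGA 0-10, higher
  = worse; muscle CMAS 0-52, lower = worse), plus a glucocorticoid dose;
* irregular visit times, denser during the first year, spanning several
  years of follow-up;
* CYC initiation as a discrete-time logistic hazard at each visit in the
  *recorded* skin score (confounding by indication on a measured,
  never-missing covariate) with a log-odds decay in time since diagnosis,
  so that starts concentrate in the first months after diagnosis;
* a single noncontinuous treatment course whose duration is drawn around
  a 5.2-month median, with no discontinuers;
* planted additive treatment effects per treatment-recency category,
  applied to visits strictly after the initiation visit (scores at the
  initiation visit are pre-infusion assessments);
* item missingness in PGA, CMAS and glucocorticoid dose, completely at
  random by default, with DAS always complete.

The initiation intercept is calibrated by bisection so the expected
treated fraction matches ``frac_treated_target`` exactly for the realised
visit schedules; assignment then uses pre-drawn uniforms, which keeps a
fixed seed bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    EVER_FEATURES,
    MED_FLAGS,
    SCORE_RANGES,
    CohortTable,
    SplitTime,
    split_time_categories,
)
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ReplicateResult",
    "simulate_cohort",
    "plant_missingness",
    "simulate_replicates",
    "write_truth",
]

# per-patient static flag models: probability = expit(a + b * (baseline severity - 6.5));
# positive b ties the flag to severity, mirroring the medication/feature
# imbalance seen between treated and untreated registry patients
_MED_FLAG_MODELS = {
    "oral_gc": (2.2, 0.3),
    "iv_gc": (-0.1, 0.5),
    "mtx": (2.5, 0.2),
    "ivig": (-1.7, 0.5),
    "hcq": (-1.2, 0.3),
    "aza": (-1.8, 0.2),
    "mmf": (-2.7, 0.3),
    "biologic": (-1.9, 0.5),
}
_FEATURE_MODELS = {
    "calcinosis": (-1.2, 0.4),
    "ulceration": (-1.5, 0.6),
    "lipoatrophy": (-1.8, 0.3),
    "abnormal_respiration": (-1.6, 0.5),
    "edema": (0.1, 0.4),
}


def _default_missingness() -> dict:
    # long-run item-missingness rates: none for the skin score, roughly a
    # quarter of PGA and CMAS values, over half of precise steroid doses
    return {"das": 0.0, "pga": 0.25, "cmas": 0.26, "gc_dose": 0.55}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Effects are additive shifts (in the outcome's own units) applied per
    treatment-recency category; keys are :class:`SplitTime` members, absent
    keys mean no effect.  ``confounding_strength`` is the initiation
    log-odds per unit of severity on the 0-10 global scale (the hazard uses
    the recorded skin score rescaled to that scale).
    """

    n_patients: int = 200
    frac_treated_target: float = 0.28
    confounding_strength: float = 0.4
    initiation_time_slope: float = -0.25  # log-odds per month since diagnosis
    baseline_logodds_offset: float = -1.5  # extra log-odds for receipt at the first visit
    effect_das: Mapping[SplitTime, float] = field(
        default_factory=lambda: {SplitTime.CYC_GT_12MO: -1.19}
    )
    effect_pga: Mapping[SplitTime, float] = field(
        default_factory=lambda: {SplitTime.CYC_GT_12MO: -0.66}
    )
    effect_cmas: Mapping[SplitTime, float] = field(default_factory=dict)
    followup_years: float = 7.5  # midpoint; per-patient follow-up is uniform around it
    visit_gap_early: float = 1.2  # mean months between visits in year 1
    visit_gap_late: float = 4.0  # mean months between visits after year 1
    baseline_severity_mean: float = 6.5
    baseline_severity_sd: float = 1.5
    trend_slope: float = 0.015  # severity units of natural improvement per month
    deviation_sd: float = 0.9  # stationary sd of mean-reverting deviations
    deviation_reversion: float = 0.06  # per-month reversion rate of deviations
    das_noise: float = 0.45
    pga_noise: float = 0.8
    cmas_noise: float = 3.5
    cyc_duration_median: float = 5.2  # months
    cyc_duration_log_sd: float = 0.2565  # matches an IQR of about 4.6-6.5 months
    cyc_duration_range: tuple = (3.0, 9.0)
    missingness: Mapping[str, float] = field(default_factory=_default_missingness)
    informative_missingness: bool = False
    seed: int = 0

    def effects_for(self, outcome: str) -> dict:
        eff = {"das": self.effect_das, "pga": self.effect_pga, "cmas": self.effect_cmas}[outcome]
        full = {c: 0.0 for c in SplitTime}
        full.update({SplitTime(k): float(v) for k, v in eff.items()})
        return full

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 2:
            raise ValidationError("n_patients must be at least 2")
        if not 0 <= self.frac_treated_target <= 1:
            raise ValidationError("frac_treated_target must be in [0, 1]")
        for score, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValidationError(f"missingness rate for {score} must be in [0, 1]")
        return self


@dataclass
class SimulationTruth:
    """Everything the generator knows that the analyst must recover."""

    config: SimulationConfig
    initiation: dict  # intercept, das_coefficient, time_slope of the true hazard
    effects: dict  # outcome -> {SplitTime: shift}
    severity: pd.DataFrame  # patient_id, t, severity (latent path)
    complete_scores: pd.DataFrame  # scores before missingness was planted
    positivity_warning: bool = False


@dataclass
class ReplicateResult:
    index: int
    seed: int
    truth: SimulationTruth | None
    value: object = None
    error: Exception | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _visit_times(rng, followup, gap_early, gap_late) -> np.ndarray:
    """Renewal-process visit times, denser in the first year, starting at 0."""
    n_early = max(int(24 / gap_early), 4)
    early = np.maximum(rng.gamma(2.0, gap_early / 2.0, size=n_early), 0.25)
    t_early = np.cumsum(early)
    t_early = t_early[t_early < min(12.0, followup)]
    last = t_early[-1] if t_early.size else 0.0
    n_late = max(int((followup - last) / gap_late * 2) + 8, 4)
    late = np.maximum(rng.gamma(2.0, gap_late / 2.0, size=n_late), 0.5)
    t_late = last + np.cumsum(late)
    t_late = t_late[t_late <= followup]
    return np.concatenate([[0.0], t_early, t_late])


def _draw_duration(rng, cfg: SimulationConfig) -> float:
    lo, hi = cfg.cyc_duration_range
    mu = np.log(cfg.cyc_duration_median)
    for _ in range(200):
        d = float(rng.lognormal(mu, cfg.cyc_duration_log_sd))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, SimulationTruth]:
    """Generate one cohort plus its ground-truth record.

    See the module docstring for the generating model.  A fixed
    ``config.seed`` yields a bit-identical cohort and truth record.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    rows = []  # one dict per patient holding its arrays
    fy = cfg.followup_years * 12.0
    rho = np.exp(-cfg.deviation_reversion)
    for i in range(n):
        pid = f"P{i:04d}"
        sex = "female" if rng.random() < 0.665 else "male"
        age = float(np.clip(rng.gamma(4.0, 2.0), 1.0, 16.0))
        s0 = cfg.baseline_severity_mean + cfg.baseline_severity_sd * rng.standard_normal()
        s0 = float(np.clip(s0 - 0.08 * (age - 8.0), 4.0, 9.5))
        followup = float(rng.uniform(0.55, 1.45) * fy)
        t = _visit_times(rng, followup, cfg.visit_gap_early, cfg.visit_gap_late)
        k = t.size
        # mean-reverting deviations around the linear severity trend
        dev = np.empty(k)
        dev[0] = cfg.deviation_sd * rng.standard_normal()
        z = rng.standard_normal(k - 1) if k > 1 else np.empty(0)
        for j in range(1, k):
            r = rho ** (t[j] - t[j - 1])
            dev[j] = r * dev[j - 1] + cfg.deviation_sd * np.sqrt(1 - r * r) * z[j - 1]
        sev = s0 - cfg.trend_slope * t + dev
        das = np.clip(0.5 * sev + cfg.das_noise * rng.standard_normal(k), *SCORE_RANGES["das"])
        pga = np.clip(sev + cfg.pga_noise * rng.standard_normal(k), *SCORE_RANGES["pga"])
        cmas = np.clip(
            52.0 - 4.2 * sev + cfg.cmas_noise * rng.standard_normal(k), *SCORE_RANGES["cmas"]
        )
        gc = np.clip(3.5 * sev * np.exp(-t / 10.0) + 3.0 * rng.standard_normal(k), 0.0, 80.0)
        u = rng.random(k)  # initiation uniforms, consumed after calibration
        duration = _draw_duration(rng, cfg)
        flags = {
            m: bool(rng.random() < expit(a + b * (s0 - 6.5)))
            for m, (a, b) in _MED_FLAG_MODELS.items()
        }
        feats = {
            f: bool(rng.random() < expit(a + b * (s0 - 6.5)))
            for f, (a, b) in _FEATURE_MODELS.items()
        }
        rows.append(
            dict(pid=pid, sex=sex, age=age, t=t, sev=sev, das=das, pga=pga, cmas=cmas,
                 gc=gc, u=u, duration=duration, flags=flags, feats=feats)
        )

    # calibrate the initiation intercept so the expected treated fraction,
    # given the realised visit schedules and scores, hits the target
    base_logits = []
    for r in rows:
        bl = 2.0 * cfg.confounding_strength * r["das"] + cfg.initiation_time_slope * r["t"]
        bl[0] += cfg.baseline_logodds_offset  # receipt at first visit is its own sub-model
        base_logits.append(bl)

    def treated_fraction(c: float) -> float:
        p = [1.0 - np.prod(1.0 - expit(c + bl)) for bl in base_logits]
        return float(np.mean(p))

    lo, hi = -30.0, 10.0
    if cfg.frac_treated_target <= 0:
        intercept = -np.inf
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if treated_fraction(mid) < cfg.frac_treated_target:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)

    positivity_warning = False
    effects = {o: cfg.effects_for(o) for o in ("das", "pga", "cmas")}

    patient_rows, visit_frames, sev_frames = [], [], []
    for r, bl in zip(rows, base_logits):
        h = expit(intercept + bl) if np.isfinite(intercept) else np.zeros_like(bl)
        if np.isfinite(intercept) and (np.any(h <= 0.0) or np.any(h >= 1.0)):
            positivity_warning = True
        started = np.nonzero(r["u"] < h)[0]
        cyc_start = cyc_stop = np.nan
        if started.size:
            cyc_start = float(r["t"][started[0]])
            cyc_stop = cyc_start + r["duration"]
        on_cyc = (
            (r["t"] >= cyc_start) & (r["t"] < cyc_stop)
            if not np.isnan(cyc_start)
            else np.zeros(r["t"].size, dtype=bool)
        )
        das, pga, cmas = r["das"].copy(), r["pga"].copy(), r["cmas"].copy()
        if not np.isnan(cyc_start):
            post = r["t"] > cyc_start  # initiation-visit scores are pre-infusion
            cats = split_time_categories(r["t"][post], np.full(post.sum(), cyc_start))
            for name, arr in (("das", das), ("pga", pga), ("cmas", cmas)):
                shift = np.array([effects[name][SplitTime(c)] for c in cats])
                arr[post] = np.clip(arr[post] + shift, *SCORE_RANGES[name])
        patient_rows.append(
            dict(patient_id=r["pid"], sex=r["sex"], age_at_diagnosis=r["age"],
                 cyc_start=cyc_start, cyc_stop=cyc_stop, **r["feats"])
        )
        k = r["t"].size
        visit_frames.append(
            pd.DataFrame(
                dict(patient_id=r["pid"], t=r["t"], das=das, pga=pga, cmas=cmas,
                     gc_dose=r["gc"], on_cyc=on_cyc,
                     **{m: np.full(k, v) for m, v in r["flags"].items()})
            )
        )
        sev_frames.append(pd.DataFrame(dict(patient_id=r["pid"], t=r["t"], severity=r["sev"])))

    patients = pd.DataFrame(patient_rows)[
        ["patient_id", "sex", "age_at_diagnosis", "cyc_start", "cyc_stop"] + EVER_FEATURES
    ]
    visits = pd.concat(visit_frames, ignore_index=True)[
        ["patient_id", "t", "das", "pga", "cmas", "gc_dose", "on_cyc"] + MED_FLAGS
    ]
    cohort = CohortTable(patients, visits).validate()
    truth = SimulationTruth(
        config=cfg,
        initiation={
            "intercept": float(intercept),
            "das_coefficient": 2.0 * cfg.confounding_strength,
            "time_slope": cfg.initiation_time_slope,
        },
        effects={o: {c.value: v for c, v in eff.items()} for o, eff in effects.items()},
        severity=pd.concat(sev_frames, ignore_index=True),
        complete_scores=visits[["patient_id", "t", "das", "pga", "cmas", "gc_dose"]].copy(),
        positivity_warning=positivity_warning,
    )
    cohort = plant_missingness(
        cohort, cfg.missingness, rng, informative=cfg.informative_missingness
    )
    return cohort, truth


def plant_missingness(
    cohort: CohortTable,
    rates: Mapping[str, float],
    rng_or_seed,
    informative: bool = False,
) -> CohortTable:
    """Return a copy of ``cohort`` with score cells set missing at the given
    per-score probabilities.

    The skin DAS may never be made missing (its rate must be 0).  With
    ``informative=True`` the per-visit missingness odds for PGA, CMAS and
    gc_dose are shifted by the visit's own PGA (sicker visits more likely
    incomplete), a sensitivity switch for missing-not-at-random behaviour.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    for score, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"missingness rate for {score} must be in [0, 1]")
        if score == "das" and rate > 0:
            raise ValidationError("the skin DAS is always recorded; its rate must be 0")
    out = cohort.copy()
    v = out.visits
    for score in ("pga", "cmas", "gc_dose"):
        rate = float(rates.get(score, 0.0))
        if rate <= 0.0:
            continue
        if informative:
            shift = 0.25 * (v["pga"].fillna(v["pga"].mean()) - 5.0)
            p = expit(logit(np.clip(rate, 1e-9, 1 - 1e-9)) + shift)
        else:
            p = np.full(len(v), rate)
        v.loc[rng.random(len(v)) < p, score] = np.nan
    return out


def simulate_replicates(
    config: SimulationConfig,
    n_reps: int,
    pipeline: Callable[[CohortTable, SimulationTruth], object],
) -> list[ReplicateResult]:
    """Run ``pipeline`` on ``n_reps`` independent cohorts.

    Replicate seeds are derived deterministically from ``config.seed``, so a
    fixed master seed reproduces every replicate.  A pipeline failure on one
    replicate is recorded in its :class:`ReplicateResult` and the run
    continues.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    child_seeds = (
        np.random.SeedSequence(config.seed).generate_state(n_reps, dtype=np.uint32)
        % np.uint32(2**31)
    )
    results = []
    for i, seed in enumerate(child_seeds):
        sub = replace(config, seed=int(seed))
        cohort, truth = simulate_cohort(sub)
        try:
            value = pipeline(cohort, truth)
            results.append(ReplicateResult(i, int(seed), truth, value=value))
        except Exception as err:  # noqa: BLE001 - recorded per replicate
            results.append(ReplicateResult(i, int(seed), truth, error=err))
    return results


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the truth record as a JSON sidecar (config echo, true hazard,
    planted effects, latent severity path)."""
    cfg = dataclasses.asdict(truth.config)
    for key in ("effect_das", "effect_pga", "effect_cmas"):
        cfg[key] = {SplitTime(k).value: v for k, v in cfg[key].items()}
    payload = {
        "config": cfg,
        "initiation": truth.initiation,
        "effects": truth.effects,
        "positivity_warning": truth.positivity_warning,
        "severity": truth.severity.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
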