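"""Cohort container, long-format table I/O, eligibility filtering and
treatment-recency ("split time") coding.

A cohort is a pair of tables: one row per patient (demographics, treatment
course dates, ever-recorded clinical features) and one row per patient-visit
(disease-activity scores, medication flags, time since diagnosis).  All times
are months since diagnosis; diagnosis is time 0.  Scores follow the usual
juvenile dermatomyositis conventions: skin DAS in [0, 5] and physician's
global assessment (PGA) in [0, 10] with higher = worse, muscle CMAS in
[0, 52] with lower = worse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, SchemaError, ValidationError

__all__ = [
    "SplitTime",
    "SPLIT_TIME_ORDER",
    "CohortTable",
    "LoadReport",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "nearest_visit",
    "split_time",
    "split_time_categories",
]


class SplitTime(str, enum.Enum):
    """Recency of cyclophosphamide (CYC) initiation relative to a visit.

    The four categories partition every patient-visit: untreated follow-up
    (including visits before a later initiation), visits within 6 months of
    starting CYC (the treatment course is typically still running), 6-12
    months after starting (course recently completed), and more than 12
    months after starting.
    """

    NEVER_NOT_YET = "never_not_yet"
    CYC_LE_6MO = "cyc_le_6mo"
    CYC_6_12MO = "cyc_6_12mo"
    CYC_GT_12MO = "cyc_gt_12mo"


SPLIT_TIME_ORDER = (
    SplitTime.NEVER_NOT_YET,
    SplitTime.CYC_LE_6MO,
    SplitTime.CYC_6_12MO,
    SplitTime.CYC_GT_12MO,
)

#: categories that carry a treatment-effect estimate (reference omitted)
TREATED_CATEGORIES = SPLIT_TIME_ORDER[1:]

SCORE_RANGES = {"das": (0.0, 5.0), "pga": (0.0, 10.0), "cmas": (0.0, 52.0)}

MED_FLAGS = ["oral_gc", "iv_gc", "mtx", "ivig", "hcq", "aza", "mmf", "biologic"]
EVER_FEATURES = ["calcinosis", "ulceration", "lipoatrophy", "abnormal_respiration", "edema"]

# file column -> internal column
_VISIT_FILE_COLUMNS = {
    "patient_id": "patient_id",
    "t_months": "t",
    "das": "das",
    "pga": "pga",
    "cmas": "cmas",
    "gc_dose_mg_day": "gc_dose",
    "on_cyc": "on_cyc",
    **{m: m for m in MED_FLAGS},
}
_PATIENT_FILE_COLUMNS = {
    "patient_id": "patient_id",
    "sex": "sex",
    "age_at_diagnosis_years": "age_at_diagnosis",
    "cyc_start_months": "cyc_start",
    "cyc_stop_months": "cyc_stop",
    **{f: f for f in EVER_FEATURES},
}

VISIT_COLUMNS = list(_VISIT_FILE_COLUMNS.values())
PATIENT_COLUMNS = list(_PATIENT_FILE_COLUMNS.values())

_VISIT_NUMERIC = ["t", "das", "pga", "cmas", "gc_dose"]
_PATIENT_NUMERIC = ["age_at_diagnosis", "cyc_start", "cyc_stop"]
_VISIT_BOOL = ["on_cyc"] + MED_FLAGS
_PATIENT_BOOL = EVER_FEATURES


def split_time(t: float, cyc_start: float | None) -> SplitTime:
    """Categorise a single visit time by treatment recency.

    ``cyc_start`` absent (``None`` or NaN), or ``t`` before it, codes as
    never/not-yet.  Boundaries are half-open so the categories partition:
    exactly 6 months after initiation still counts as "within 6 months",
    exactly 12 as "6-12 months".
    """
    if t < 0:
        raise ValidationError(f"visit time must be nonnegative, got t={t}")
    if cyc_start is None or (isinstance(cyc_start, float) and np.isnan(cyc_start)):
        return SplitTime.NEVER_NOT_YET
    since = t - cyc_start
    if since < 0:
        return SplitTime.NEVER_NOT_YET
    if since <= 6:
        return SplitTime.CYC_LE_6MO
    if since <= 12:
        return SplitTime.CYC_6_12MO
    return SplitTime.CYC_GT_12MO


def split_time_categories(t, cyc_start) -> pd.Categorical:
    """Vectorised :func:`split_time` over aligned arrays of visit times and
    per-visit CYC start times (NaN = never treated)."""
    t = np.asarray(t, dtype=float)
    start = np.asarray(cyc_start, dtype=float)
    if np.any(t < 0):
        raise ValidationError("visit times must be nonnegative")
    since = t - start
    out = np.full(t.shape, SplitTime.NEVER_NOT_YET.value, dtype=object)
    with np.errstate(invalid="ignore"):
        out[(since >= 0) & (since <= 6)] = SplitTime.CYC_LE_6MO.value
        out[(since > 6) & (since <= 12)] = SplitTime.CYC_6_12MO.value
        out[since > 12] = SplitTime.CYC_GT_12MO.value
    return pd.Categorical(out, categories=[c.value for c in SPLIT_TIME_ORDER], ordered=True)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_cohort`: row counts and cells that could
    not be parsed as numbers and were recorded as missing."""

    n_patients: int = 0
    n_visits: int = 0
    coerced_cells: dict = field(default_factory=dict)


@dataclass
class CohortTable:
    """A patient table plus a visit table, the pipeline's common currency.

    ``patients`` has one row per patient: patient_id, sex ('female'/'male'),
    age_at_diagnosis (years), cyc_start / cyc_stop (months since diagnosis,
    NaN if never treated), and boolean ever-recorded features.  ``visits``
    has one row per patient-visit sorted by (patient_id, t): scores, gc_dose
    (mg/day), on_cyc and per-visit medication flags.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def treated_ids(self) -> pd.Index:
        p = self.patients
        return pd.Index(p.loc[p["cyc_start"].notna(), "patient_id"])

    def copy(self) -> "CohortTable":
        return CohortTable(self.patients.copy(), self.visits.copy())

    def merged(self) -> pd.DataFrame:
        """Visits joined with their patient rows (suffix-free; patient_id key)."""
        return self.visits.merge(self.patients, on="patient_id", how="left", validate="m:1")

    def validate(self) -> "CohortTable":
        """Check every documented invariant; raise ValidationError/SchemaError
        on the first violation.  Returns self so calls can be chained."""
        p, v = self.patients, self.visits
        for col in PATIENT_COLUMNS:
            if col not in p.columns:
                raise SchemaError(f"patient table missing column '{col}'")
        for col in VISIT_COLUMNS:
            if col not in v.columns:
                raise SchemaError(f"visit table missing column '{col}'")
        if p["patient_id"].duplicated().any():
            dup = p.loc[p["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id '{dup}' in patient table")
        bad_sex = ~p["sex"].isin(["female", "male"])
        if bad_sex.any():
            raise ValidationError(
                f"sex must be 'female' or 'male', got {p.loc[bad_sex, 'sex'].iloc[0]!r}"
            )
        unknown = set(v["patient_id"]) - set(p["patient_id"])
        if unknown:
            raise ValidationError(f"visits reference unknown patient_id(s): {sorted(unknown)[:5]}")
        if v.duplicated(["patient_id", "t"]).any():
            row = v[v.duplicated(["patient_id", "t"])].iloc[0]
            raise ValidationError(
                f"duplicate visit for patient '{row['patient_id']}' at t={row['t']}"
            )
        if (v["t"] < 0).any():
            raise ValidationError("visit times must be nonnegative")
        srt = v.sort_values(["patient_id", "t"], kind="mergesort")
        if not np.array_equal(srt.index.to_numpy(), v.index.to_numpy()):
            raise ValidationError("visits must be sorted by (patient_id, t)")
        for col, (lo, hi) in SCORE_RANGES.items():
            x = v[col]
            bad = x.notna() & ((x < lo) | (x > hi))
            if bad.any():
                i = bad.idxmax()
                raise ValidationError(
                    f"{col}={v.loc[i, col]} out of range [{lo}, {hi}] "
                    f"(patient '{v.loc[i, 'patient_id']}', row {i})"
                )
        gd = v["gc_dose"]
        if (gd.notna() & (gd < 0)).any():
            raise ValidationError("gc_dose must be nonnegative")
        # treatment-course invariants
        has_stop = p["cyc_stop"].notna()
        if (has_stop & p["cyc_start"].isna()).any():
            pid = p.loc[has_stop & p["cyc_start"].isna(), "patient_id"].iloc[0]
            raise ValidationError(f"patient '{pid}' has cyc_stop without cyc_start")
        if (p["cyc_start"] < 0).any():
            raise ValidationError("cyc_start must be nonnegative")
        both = p["cyc_start"].notna() & has_stop
        if (p.loc[both, "cyc_stop"] <= p.loc[both, "cyc_start"]).any():
            raise ValidationError("cyc_stop must be strictly after cyc_start")
        # on_cyc must equal cyc_start <= t < cyc_stop (single course)
        m = v.merge(p[["patient_id", "cyc_start", "cyc_stop"]], on="patient_id", how="left")
        expected = (m["t"] >= m["cyc_start"]) & (m["t"] < m["cyc_stop"])
        expected = expected.fillna(False).to_numpy()
        observed = m["on_cyc"].to_numpy(dtype=bool)
        if not np.array_equal(expected, observed):
            # distinguish an apparent second course from a plain inconsistency
            runs = (
                m.assign(on=observed)
                .groupby("patient_id")["on"]
                .apply(lambda s: int((s.astype(int).diff() == 1).sum() + int(s.iloc[0])))
            )
            if (runs > 1).any():
                pid = runs[runs > 1].index[0]
                raise ValidationError(
                    f"patient '{pid}' shows more than one CYC course; re-treatment is "
                    "not supported (single-course protocol, split-time coding undefined)"
                )
            i = int(np.nonzero(expected != observed)[0][0])
            raise ValidationError(
                f"on_cyc inconsistent with [cyc_start, cyc_stop) for patient "
                f"'{m.loc[i, 'patient_id']}' at t={m.loc[i, 't']}"
            )
        return self


def _coerce_numeric(df: pd.DataFrame, cols, report: LoadReport) -> None:
    for col in cols:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        lost = int((num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")).sum())
        if lost:
            report.coerced_cells[col] = report.coerced_cells.get(col, 0) + lost
        df[col] = num


def _coerce_bool(df: pd.DataFrame, cols) -> None:
    truthy = {"true", "1", "1.0", "yes"}
    falsy = {"false", "0", "0.0", "no", ""}
    for col in cols:
        s = df[col].astype(str).str.strip().str.lower().replace("nan", "")
        bad = ~s.isin(truthy | falsy)
        if bad.any():
            raise ValidationError(f"column '{col}' has non-boolean value {df.loc[bad.idxmax(), col]!r}")
        df[col] = s.isin(truthy)


def read_cohort(visits_path, patients_path) -> tuple[CohortTable, LoadReport]:
    """Read a cohort from its two delimited text files.

    Score cells that are empty are missing values; score cells that are
    present but unparseable are recorded as missing and counted in the
    returned :class:`LoadReport`.  All structural invariants are checked.
    """
    report = LoadReport()
    visits = pd.read_csv(visits_path, dtype=str)
    patients = pd.read_csv(patients_path, dtype=str)
    for name, frame, mapping in (
        ("visit", visits, _VISIT_FILE_COLUMNS),
        ("patient", patients, _PATIENT_FILE_COLUMNS),
    ):
        missing = [c for c in mapping if c not in frame.columns]
        if missing:
            raise SchemaError(f"{name} file missing mandatory column(s): {missing}")
    visits = visits.rename(columns=_VISIT_FILE_COLUMNS)[VISIT_COLUMNS]
    patients = patients.rename(columns=_PATIENT_FILE_COLUMNS)[PATIENT_COLUMNS]
    _coerce_numeric(visits, _VISIT_NUMERIC, report)
    _coerce_numeric(patients, _PATIENT_NUMERIC, report)
    if visits["t"].isna().any():
        raise ValidationError("visit times (t_months) must all be parseable numbers")
    _coerce_bool(visits, _VISIT_BOOL)
    _coerce_bool(patients, _PATIENT_BOOL)
    visits = visits.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    patients = patients.reset_index(drop=True)
    cohort = CohortTable(patients, visits).validate()
    report.n_patients = cohort.n_patients
    report.n_visits = len(visits)
    return cohort, report


def write_cohort(cohort: CohortTable, visits_path, patients_path) -> None:
    """Write the two delimited text files; inverse of :func:`read_cohort`."""
    inv_v = {v: k for k, v in _VISIT_FILE_COLUMNS.items()}
    inv_p = {v: k for k, v in _PATIENT_FILE_COLUMNS.items()}
    cohort.visits.rename(columns=inv_v).to_csv(visits_path, index=False)
    cohort.patients.rename(columns=inv_p).to_csv(patients_path, index=False)


def apply_eligibility(
    cohort: CohortTable, max_first_visit_months: float = 3.0
) -> tuple[CohortTable, pd.DataFrame]:
    """Keep incident cases with an analysable treatment history.

    Excludes patients whose first recorded visit is strictly more than
    ``max_first_visit_months`` after diagnosis (prevalent cases whose early
    disease is unrecorded) and patients who evidently received CYC but whose
    start date is unknown (on_cyc recorded with no cyc_start).  Returns the
    filtered cohort and an exclusion report with one row per excluded
    patient and the reason.  Raises :class:`EmptyCohortError` if nobody is
    retained.
    """
    first_t = cohort.visits.groupby("patient_id")["t"].min()
    ever_on = cohort.visits.groupby("patient_id")["on_cyc"].any()
    reasons = []
    for _, row in cohort.patients.iterrows():
        pid = row["patient_id"]
        if first_t.get(pid, np.inf) > max_first_visit_months:
            reasons.append(
                (pid, f"first recorded visit at {first_t[pid]:g} months exceeds "
                      f"{max_first_visit_months:g} months from diagnosis")
            )
        elif ever_on.get(pid, False) and pd.isna(row["cyc_start"]):
            reasons.append((pid, "received CYC but date of starting CYC is unknown"))
    excluded = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    keep = ~cohort.patients["patient_id"].isin(excluded["patient_id"])
    patients = cohort.patients[keep].reset_index(drop=True)
    if patients.empty:
        raise EmptyCohortError("no patients remain after eligibility filtering")
    visits = (
        cohort.visits[cohort.visits["patient_id"].isin(patients["patient_id"])]
        .reset_index(drop=True)
    )
    return CohortTable(patients, visits), excluded


def nearest_visit(
    visits: pd.DataFrame, nominal_month: float, window: float = 2.0, origin: float = 0.0
) -> pd.Series | None:
    """Pick one patient's visit closest to a nominal time point.

    ``visits`` is a single patient's visit frame (sorted by t).  Times are
    measured relative to ``origin`` (e.g. the CYC start date for the
    descriptive analysis).  Returns the row minimising |t - origin -
    nominal| among rows within ``window`` months, or None if no visit
    qualifies; equidistant ties go to the earlier visit.
    """
    if visits.empty:
        return None
    dev = (visits["t"] - origin - nominal_month).to_numpy(dtype=float)
    ok = np.abs(dev) <= window
    if not ok.any():
        return None
    cand = visits[ok]
    adev = np.abs(dev[ok])
    best = adev.min()
    # ties resolved to the earlier visit: rows are t-sorted, argmax finds first
    sel = cand[adev <= best + 1e-12].iloc[0]
    return sel
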