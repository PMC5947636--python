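import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from jdmsm.cohort import CohortTable
from jdmsm.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cohort(patients_spec):
    """Build a small cohort from a compact spec.

    ``patients_spec`` maps patient_id -> dict with keys: visits (list of t),
    optional cyc (start, stop), optional scores dict col -> list, optional
    sex/age.  Scores default to mid-range constants; med flags to False.
    """
    prows, vrows = [], []
    for pid, spec in patients_spec.items():
        start, stop = spec.get("cyc", (np.nan, np.nan))
        prows.append(
            dict(patient_id=pid, sex=spec.get("sex", "female"),
                 age_at_diagnosis=spec.get("age", 7.0), cyc_start=start, cyc_stop=stop,
                 calcinosis=False, ulceration=False, lipoatrophy=False,
                 abnormal_respiration=False, edema=False)
        )
        ts = spec["visits"]
        scores = spec.get("scores", {})
        for i, t in enumerate(ts):
            on = (not np.isnan(start)) and start <= t < stop
            vrows.append(
                dict(patient_id=pid, t=float(t),
                     das=scores.get("das", [2.0] * len(ts))[i],
                     pga=scores.get("pga", [4.0] * len(ts))[i],
                     cmas=scores.get("cmas", [30.0] * len(ts))[i],
                     gc_dose=scores.get("gc_dose", [10.0] * len(ts))[i],
                     on_cyc=on, oral_gc=True, iv_gc=False, mtx=True, ivig=False,
                     hcq=False, aza=False, mmf=False, biologic=False)
            )
    patients = pd.DataFrame(prows)
    visits = pd.DataFrame(vrows).sort_values(["patient_id", "t"]).reset_index(drop=True)
    return CohortTable(patients, visits)


@pytest.fixture
def tiny_cohort():
    """Three patients: one treated, one never treated, one late first visit."""
    return make_cohort(
        {
            "A": dict(visits=[0, 1, 3, 7, 14, 20], cyc=(1.0, 6.5)),
            "B": dict(visits=[0.5, 4, 9, 15]),
            "C": dict(visits=[4.0, 8, 12]),
        }
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """One default synthetic cohort shared by read-only tests."""
    cohort, truth = simulate_cohort(SimulationConfig(seed=7))
    return cohort, truth
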