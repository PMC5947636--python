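"""Cohort container, I/O round-trip, eligibility and split-time coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jdmsm.cohort import (
    SPLIT_TIME_ORDER,
    CohortTable,
    SplitTime,
    apply_eligibility,
    nearest_visit,
    read_cohort,
    split_time,
    split_time_categories,
    write_cohort,
)
from jdmsm.errors import EmptyCohortError, SchemaError, ValidationError

from conftest import make_cohort


class TestSplitTime:
    @pytest.mark.parametrize(
        "t,start,expected",
        [
            (10.0, None, SplitTime.NEVER_NOT_YET),
            (2.0, 5.0, SplitTime.NEVER_NOT_YET),
            (8.0, 5.0, SplitTime.CYC_LE_6MO),   # 3 months after start
            (14.0, 5.0, SplitTime.CYC_6_12MO),  # 9 months after start
            (20.0, 5.0, SplitTime.CYC_GT_12MO),  # 15 months after start
            (11.0, 5.0, SplitTime.CYC_LE_6MO),  # exactly 6: half-open boundary
            (17.0, 5.0, SplitTime.CYC_6_12MO),  # exactly 12
            (0.0, 0.0, SplitTime.CYC_LE_6MO),   # treated from diagnosis
        ],
    )
    def test_category_boundaries(self, t, start, expected):
        assert split_time(t, start) is expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            split_time(-1.0, None)

    @given(
        start=st.one_of(st.none(), st.floats(0, 30)),
        ts=st.lists(st.floats(0, 120), min_size=2, max_size=30),
    )
    def test_categories_monotone_along_trajectory(self, start, ts):
        """Categories never reverse as a patient's follow-up advances."""
        ts = sorted(ts)
        order = [SPLIT_TIME_ORDER.index(split_time(t, start)) for t in ts]
        assert order == sorted(order)

    def test_vectorised_matches_scalar(self):
        t = np.array([0.0, 3.0, 8.0, 14.0, 40.0])
        start = np.array([np.nan, 2.0, 2.0, 2.0, 2.0])
        vec = split_time_categories(t, start)
        scal = [split_time(ti, None if np.isnan(s) else s) for ti, s in zip(t, start)]
        assert list(vec) == [c.value for c in scal]


class TestNearestVisit:
    def _visits(self, ts):
        return pd.DataFrame({"t": ts, "das": np.arange(len(ts), dtype=float)})

    def test_picks_closest_within_window(self):
        v = nearest_visit(self._visits([4.5, 7.9]), 6)
        assert v["t"] == 4.5  # 1.5 < 1.9

    def test_none_outside_window(self):
        assert nearest_visit(self._visits([8.5]), 6) is None

    def test_tie_goes_to_earlier_visit(self):
        v = nearest_visit(self._visits([5.0, 7.0]), 6)
        assert v["t"] == 5.0

    @given(
        ts=st.lists(st.floats(0, 40), min_size=1, max_size=15),
        nominal=st.sampled_from([0, 6, 12, 24]),
    )
    def test_never_returns_outside_window(self, ts, nominal):
        v = nearest_visit(self._visits(sorted(ts)), nominal, window=2.0)
        if v is not None:
            assert abs(v["t"] - nominal) <= 2.0


class TestIO:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        """write_cohort then read_cohort reproduces every field exactly."""
        vp, pp = tmp_path / "visits.csv", tmp_path / "patients.csv"
        write_cohort(tiny_cohort, vp, pp)
        back, report = read_cohort(vp, pp)
        pd.testing.assert_frame_equal(back.visits, tiny_cohort.visits)
        pd.testing.assert_frame_equal(back.patients, tiny_cohort.patients)
        assert report.n_patients == 3 and report.coerced_cells == {}

    def test_empty_cell_is_missing(self, tiny_cohort, tmp_path):
        vp, pp = tmp_path / "v.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, vp, pp)
        txt = vp.read_text().splitlines()
        header = txt[0].split(",")
        row = txt[1].split(",")
        row[header.index("pga")] = ""
        vp.write_text("\n".join([txt[0], ",".join(row)] + txt[2:]))
        back, report = read_cohort(vp, pp)
        assert np.isnan(back.visits.loc[0, "pga"])
        assert report.coerced_cells == {}  # empty is missing, not unparseable

    def test_unparseable_cell_counted(self, tiny_cohort, tmp_path):
        vp, pp = tmp_path / "v.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, vp, pp)
        txt = vp.read_text().splitlines()
        header = txt[0].split(",")
        row = txt[1].split(",")
        row[header.index("cmas")] = "forty"
        vp.write_text("\n".join([txt[0], ",".join(row)] + txt[2:]))
        back, report = read_cohort(vp, pp)
        assert np.isnan(back.visits.loc[0, "cmas"])
        assert report.coerced_cells == {"cmas": 1}

    def test_out_of_range_score_names_row(self, tiny_cohort, tmp_path):
        vp, pp = tmp_path / "v.csv", tmp_path / "p.csv"
        bad = tiny_cohort.copy()
        bad.visits.loc[2, "das"] = 7.0
        write_cohort(bad, vp, pp)
        with pytest.raises(ValidationError, match="das=7.*range"):
            read_cohort(vp, pp)

    def test_missing_column_names_column(self, tiny_cohort, tmp_path):
        vp, pp = tmp_path / "v.csv", tmp_path / "p.csv"
        write_cohort(tiny_cohort, vp, pp)
        df = pd.read_csv(vp).drop(columns=["cmas"])
        df.to_csv(vp, index=False)
        with pytest.raises(SchemaError, match="cmas"):
            read_cohort(vp, pp)

    def test_duplicate_visit_rejected(self, tiny_cohort, tmp_path):
        vp, pp = tmp_path / "v.csv", tmp_path / "p.csv"
        dup = tiny_cohort.copy()
        dup.visits = pd.concat([dup.visits, dup.visits.iloc[[0]]], ignore_index=True)
        dup.visits = dup.visits.sort_values(["patient_id", "t"]).reset_index(drop=True)
        write_cohort(dup, vp, pp)
        with pytest.raises(ValidationError, match="duplicate visit"):
            read_cohort(vp, pp)


class TestValidation:
    def test_re_treatment_rejected(self):
        c = make_cohort({"A": dict(visits=[0, 2, 5, 9, 12], cyc=(1.0, 4.0))})
        # forge a second course: on_cyc flips back on outside [start, stop)
        c.visits.loc[c.visits["t"] == 9.0, "on_cyc"] = True
        with pytest.raises(ValidationError, match="re-treatment"):
            c.validate()

    def test_cyc_stop_requires_start(self):
        c = make_cohort({"A": dict(visits=[0, 2])})
        c.patients.loc[0, "cyc_stop"] = 5.0
        with pytest.raises(ValidationError, match="cyc_stop without cyc_start"):
            c.validate()

    def test_on_cyc_must_match_interval(self):
        c = make_cohort({"A": dict(visits=[0, 2, 5], cyc=(1.0, 6.0))})
        c.visits.loc[1, "on_cyc"] = False
        with pytest.raises(ValidationError, match="on_cyc inconsistent"):
            c.validate()


class TestEligibility:
    def test_exclusion_reasons(self, tiny_cohort):
        kept, excluded = apply_eligibility(tiny_cohort)
        assert set(kept.patients["patient_id"]) == {"A", "B"}
        assert excluded.loc[0, "patient_id"] == "C"
        assert "exceeds 3" in excluded.loc[0, "reason"]

    def test_unknown_cyc_start_excluded(self):
        c = make_cohort(
            {"A": dict(visits=[0, 2, 5], cyc=(1.0, 6.0)), "B": dict(visits=[0, 3])}
        )
        c.patients.loc[0, ["cyc_start", "cyc_stop"]] = np.nan  # on_cyc stays recorded
        kept, excluded = apply_eligibility(c)
        assert list(kept.patients["patient_id"]) == ["B"]
        assert "unknown" in excluded.loc[0, "reason"]

    def test_idempotent_and_partitioning(self, tiny_cohort):
        kept, excluded = apply_eligibility(tiny_cohort)
        again, excluded2 = apply_eligibility(kept)
        assert excluded2.empty
        pd.testing.assert_frame_equal(again.patients, kept.patients)
        all_ids = set(tiny_cohort.patients["patient_id"])
        assert set(kept.patients["patient_id"]) | set(excluded["patient_id"]) == all_ids
        assert set(kept.patients["patient_id"]) & set(excluded["patient_id"]) == set()

    def test_never_cyc_early_visit_retained(self):
        c = make_cohort({"A": dict(visits=[1.0, 5.0])})
        kept, excluded = apply_eligibility(c)
        assert kept.n_patients == 1 and excluded.empty

    def test_empty_result_raises(self):
        c = make_cohort({"A": dict(visits=[4.0, 8.0])})
        with pytest.raises(EmptyCohortError):
            apply_eligibility(c)
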