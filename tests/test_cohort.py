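import datetime as dt

import numpy as np
import pytest

from emrisk.cohort import (
    Cohort,
    PatientHistory,
    build_cohort,
    prevalence_percent,
    select_cases,
    select_controls,
    summarize_cohort,
)
from emrisk.records import DiagnosticRecord

TARGET = "71400"
WINDOW = (dt.date(2000, 1, 1), dt.date(2008, 12, 31))


def rec(pid, date, code5):
    return DiagnosticRecord(pid, date, code5, code5)


@pytest.fixture
def five_record_patient():
    """Two target diagnoses; three other records straddling the index date."""
    return [
        rec("P1", "2000-06-01", "25000"),
        rec("P1", "2000-12-24", "40110"),
        rec("P1", "2001-03-01", TARGET),
        rec("P1", "2001-06-01", "49300"),  # after first target dx
        rec("P1", "2002-05-01", TARGET),
    ]


class TestSelectCases:
    def test_censors_history_at_first_target_diagnosis(
        self, five_record_patient
    ):
        cases = select_cases(
            five_record_patient, {"P1"}, TARGET, min_dx=2, window=WINDOW
        )
        assert len(cases) == 1
        case = cases[0]
        assert case.censor_date == dt.date(2001, 3, 1)
        assert case.codes == {"25000", "40110"}
        assert all(r.date < case.censor_date for r in case.records)
        assert TARGET not in case.codes

    def test_registry_membership_is_required(self, five_record_patient):
        assert select_cases(five_record_patient, {"OTHER"}, TARGET) == []

    def test_min_dx_threshold(self):
        one_dx = [rec("P1", "2001-03-01", TARGET)]
        assert select_cases(one_dx, {"P1"}, TARGET, min_dx=2) == []
        assert len(select_cases(one_dx, {"P1"}, TARGET, min_dx=1)) == 1

    def test_order_invariant(self, five_record_patient):
        shuffled = list(reversed(five_record_patient))
        a = select_cases(five_record_patient, {"P1"}, TARGET)
        b = select_cases(shuffled, {"P1"}, TARGET)
        assert a == b

    def test_empty_registry_warns(self, five_record_patient):
        with pytest.warns(UserWarning, match="empty registry"):
            assert select_cases(five_record_patient, set(), TARGET) == []


class TestSelectControls:
    def test_target_free_patient_is_control(self):
        recs = [rec("P2", "2001-01-01", "25000"),
                rec("P2", "2003-01-01", "40110"),
                rec("P2", "2004-01-01", "49300")]
        controls = select_controls(recs, set(), TARGET)
        assert [h.patient_id for h in controls] == ["P2"]
        assert controls[0].censor_date is None

    def test_subthreshold_target_patient_excluded_from_both_arms(self):
        recs = [rec("P3", "2001-01-01", TARGET),
                rec("P3", "2002-01-01", "25000")]
        assert select_cases(recs, {"P3"}, TARGET, min_dx=2) == []
        assert select_controls(recs, set(), TARGET) == []

    def test_no_records_in_window_excluded(self):
        recs = [rec("P4", "1998-01-01", "25000")]
        assert select_controls(recs, set(), TARGET, window=WINDOW) == []


class TestPatientHistory:
    def test_case_record_on_censor_date_rejected(self):
        with pytest.raises(ValueError):
            PatientHistory(
                "P1", "case",
                (rec("P1", "2001-03-01", "25000"),),
                censor_date=dt.date(2001, 3, 1),
            )

    def test_arms_must_be_disjoint(self):
        h = PatientHistory("P1", "case", (), censor_date=None)
        g = PatientHistory("P1", "control", ())
        with pytest.raises(ValueError):
            Cohort([h], [g], TARGET, WINDOW)


class TestBuildCohort:
    def test_selection_log_counts(self, five_record_patient):
        recs = five_record_patient + [
            rec("P2", "2001-01-01", "25000"),
            rec("P5", "2001-01-01", TARGET),  # sub-threshold: neither arm
        ]
        cohort = build_cohort(recs, {"P1"}, TARGET)
        log = cohort.selection_log
        assert log["patients_with_records_in_window"] == 3
        assert log["cases"] == 1
        assert log["controls"] == 1
        assert log["excluded_subthreshold_or_unregistered"] == 1
        assert log["patients_with_records_in_window"] >= log["cases"]


class TestSummarize:
    def test_prevalence_matches_published_cohort_size(self):
        # 1007 cases against 921,192 controls is a 0.1% prevalence cohort
        assert round(prevalence_percent(1007, 921192), 1) == 0.1

    def test_identical_value_vectors_give_zero_t_statistic(self):
        recs = [
            # cases A1 (1 pre-censor record) and A2 (2 pre-censor records)
            rec("A1", "2001-01-01", "25000"),
            rec("A1", "2002-01-01", TARGET), rec("A1", "2002-06-01", TARGET),
            rec("A2", "2001-01-01", "25000"), rec("A2", "2001-02-01", "40110"),
            rec("A2", "2002-01-01", TARGET), rec("A2", "2002-06-01", TARGET),
            # controls with the mirrored record counts [1, 2]
            rec("B1", "2001-01-01", "25000"),
            rec("B2", "2001-01-01", "25000"), rec("B2", "2001-02-01", "40110"),
        ]
        cohort = build_cohort(recs, {"A1", "A2"}, TARGET)
        df = summarize_cohort(cohort)
        assert df.loc["records_per_year", "statistic"] == pytest.approx(0.0)
        assert df.loc["distinct_codes", "statistic"] == pytest.approx(0.0)

    def test_balanced_2x2_gives_zero_chi2(self):
        cases, controls, female = [], [], {}
        for i in range(20):
            pid = f"P{i:03d}"
            if i < 10:
                cases.append(
                    PatientHistory(pid, "case",
                                   (rec(pid, "2001-01-01", "25000"),),
                                   dt.date(2002, 1, 1))
                )
            else:
                controls.append(
                    PatientHistory(pid, "control",
                                   (rec(pid, "2001-01-01", "25000"),))
                )
            female[pid] = i % 2 == 0  # 5 of 10 female in each arm
        cohort = Cohort(cases, controls, TARGET, WINDOW)
        df = summarize_cohort(cohort, female=female)
        assert df.loc["female_proportion", "statistic"] == pytest.approx(0.0)

    def test_single_arm_summary_has_no_statistics(self):
        controls = [PatientHistory("P1", "control",
                                   (rec("P1", "2001-01-01", "25000"),))]
        cohort = Cohort([], controls, TARGET, WINDOW)
        df = summarize_cohort(cohort)
        assert np.isnan(df.loc["records_per_year", "statistic"])


def test_censoring_invariants_on_generated_cohort(small_emr):
    """No case or control history may carry the target code; censoring strict."""
    from emrisk.records import filter_noise, read_diagnostic_records

    cfg, paths = small_emr
    clean, _ = filter_noise(read_diagnostic_records(paths["records"]))
    registry = set(open(paths["registry"]).read().split())
    cohort = build_cohort(clean, registry, cfg.target_code)
    assert cohort.cases and cohort.controls
    for h in cohort.cases:
        assert cfg.target_code not in h.codes
        if h.records:
            assert max(r.date for r in h.records) < h.censor_date
    for h in cohort.controls:
        assert cfg.target_code not in h.codes
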