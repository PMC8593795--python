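import datetime as dt

import pytest

from dilidetect import (
    DiagnosisRecord,
    LabResult,
    MedicationHistoryRecord,
    StudyConfig,
    SurgeryRecord,
    assess_patient,
    classify_severity,
    compute_cohort_counts,
    criterion1_elevation,
    criterion2_recovery,
    criterion3_decrease_during,
    criterion4_nondrug_causes,
    extract_alt_features,
)

D = dt.date
T0 = D(2020, 1, 1)


def era(start=0, end=90, pid="p1", med="M1"):
    return MedicationHistoryRecord(
        pid, med, T0 + dt.timedelta(days=start), T0 + dt.timedelta(days=end), 1, end - start + 1, 0.0
    )


def alt(day, value, pid="p1"):
    return LabResult(pid, "ALT", T0 + dt.timedelta(days=day), value=value)


class TestFeatureExtraction:
    def test_window_landmarks(self, config):
        feats = extract_alt_features(
            era(0, 90),
            [alt(-10, 20), alt(30, 300), alt(60, 150), alt(100, 60)],
            config,
        )
        assert feats.baseline_alt == 20
        assert feats.peak_alt == 300
        assert feats.peak_date == T0 + dt.timedelta(days=30)
        assert feats.max_alt == 300
        assert feats.alt_during_post_peak == 150
        assert feats.alt_after == 60
        assert feats.eligible

    def test_no_baseline_means_ineligible(self, config):
        feats = extract_alt_features(era(), [alt(30, 300), alt(100, 60)], config)
        assert feats.baseline_alt is None
        assert not feats.eligible

    def test_alt_on_end_date_counts_as_during_not_after(self, config):
        feats = extract_alt_features(era(0, 90), [alt(-1, 20), alt(90, 99)], config)
        assert feats.max_alt == 99
        assert feats.alt_after is None
        assert not feats.eligible  # nothing strictly after cessation

    def test_peak_window_clipped_at_era_end(self, config):
        # era shorter than 90 days: the peak search cannot look past the end
        feats = extract_alt_features(era(0, 20), [alt(-1, 20), alt(10, 80), alt(40, 500)], config)
        assert feats.peak_alt == 80

    def test_peak_window_excludes_beyond_90_days(self, config):
        feats = extract_alt_features(
            era(0, 200), [alt(-1, 20), alt(30, 100), alt(120, 400)], config
        )
        assert feats.peak_alt == 100  # day 120 is outside the 90-day window
        assert feats.max_alt == 400  # but still on-drug for the maximum


class TestCriteria:
    @pytest.mark.parametrize(
        "baseline,peak,expected",
        [
            (20, 50, True),  # > ULN 40 and >= 2x baseline
            (30, 55, False),  # 55 < 60 = 2x30
            (10, 40, False),  # not strictly above ULN
            (None, 300, False),  # ineligible without a baseline
        ],
    )
    def test_criterion1_elevation(self, config, baseline, peak, expected):
        assert criterion1_elevation(baseline, peak, config) is expected

    @pytest.mark.parametrize(
        "max_alt,after,expected",
        [
            (300, 120, True),  # 120 < 150 = half of max
            (300, 200, False),
            (60, 35, True),  # below ULN branch
            (300, None, False),
        ],
    )
    def test_criterion2_recovery(self, config, max_alt, after, expected):
        assert criterion2_recovery(max_alt, after, config) is expected

    @pytest.mark.parametrize(
        "peak,during,expected",
        [
            (400, 90, True),  # 90 < 100 = quarter of peak
            (400, 150, False),
            (400, None, False),  # vacuous without a post-peak on-drug ALT
            (100, 35, True),  # below ULN branch
        ],
    )
    def test_criterion3_on_drug_resolution(self, config, peak, during, expected):
        assert criterion3_decrease_during(peak, during, config) is expected

    def test_criterion4_liver_diagnosis_any_date(self, config):
        excluded, reasons = criterion4_nondrug_causes(
            [DiagnosisRecord("p1", "K71.1", D(2015, 3, 1))], [], [], T0, config
        )
        assert excluded and reasons == ("prior-liver-disease",)

    def test_criterion4_non_liver_code_not_excluded(self, config):
        excluded, _ = criterion4_nondrug_causes(
            [DiagnosisRecord("p1", "K78.0", D(2015, 3, 1)),
             DiagnosisRecord("p1", "I10", D(2015, 3, 1))],
            [], [], T0, config,
        )
        assert not excluded

    def test_criterion4_positive_serology(self, config):
        excluded, reasons = criterion4_nondrug_causes(
            [],
            [LabResult("p1", "HBS_AG", D(2019, 1, 1), qualitative="positive")],
            [],
            T0,
            config,
        )
        assert excluded and "viral-hepatitis" in reasons
        # a negative serology is not an exclusion
        excluded, _ = criterion4_nondrug_causes(
            [],
            [LabResult("p1", "HBS_AG", D(2019, 1, 1), qualitative="negative")],
            [],
            T0,
            config,
        )
        assert not excluded

    @pytest.mark.parametrize("days_before,expected", [(10, True), (14, True), (20, False), (0, True)])
    def test_criterion4_surgery_lookback(self, config, days_before, expected):
        peak_date = T0 + dt.timedelta(days=30)
        excluded, _ = criterion4_nondrug_causes(
            [], [], [SurgeryRecord("p1", peak_date - dt.timedelta(days=days_before))],
            peak_date, config,
        )
        assert excluded is expected


class TestSeverity:
    @pytest.mark.parametrize(
        "max_alt,band",
        [(250, "severe"), (200, "severe"), (100, "moderate"), (80, "moderate"),
         (45, "mild"), (40, "none"), (20, "none"), (None, "none")],
    )
    def test_bands(self, config, max_alt, band):
        assert classify_severity(max_alt, config) == band


def clean_dili_labs(pid="p1"):
    # baseline 20; peak 300 on day 30; on-drug trough 150; post-cessation 60
    return [alt(-10, 20, pid), alt(30, 300, pid), alt(60, 150, pid), alt(100, 60, pid)]


class TestAssessPatient:
    def test_clean_injury_trace_is_severe_ade(self, config):
        a = assess_patient(era(0, 90), clean_dili_labs(), [], [], config)
        assert a.is_ade and a.severity == "severe"
        assert a.criterion1 and a.criterion2
        assert not a.criterion3_excluded and not a.criterion4_excluded

    def test_liver_code_flips_to_negative(self, config):
        a = assess_patient(
            era(0, 90), clean_dili_labs(), [DiagnosisRecord("p1", "K70", D(2018, 1, 1))], [], config
        )
        assert not a.is_ade and a.criterion4_excluded and a.severity == "none"

    def test_on_drug_resolution_flips_to_negative(self, config):
        labs = [alt(-10, 20), alt(30, 300), alt(60, 50), alt(100, 30)]
        a = assess_patient(era(0, 90), labs, [], [], config)
        assert not a.is_ade and a.criterion3_excluded

    def test_exclusion_only_removes_never_adds(self, config):
        base = assess_patient(era(0, 90), clean_dili_labs(), [], [], config)
        with_dx = assess_patient(
            era(0, 90), clean_dili_labs(), [DiagnosisRecord("p1", "K75", D(2019, 1, 1))], [], config
        )
        assert base.is_ade and not with_dx.is_ade

    def test_foreign_patient_records_rejected(self, config):
        with pytest.raises(ValueError, match="passed to assessment"):
            assess_patient(era(0, 90), [alt(-1, 20, pid="other")], [], [], config)

    def test_determinism(self, config):
        a1 = assess_patient(era(0, 90), clean_dili_labs(), [], [], config)
        a2 = assess_patient(era(0, 90), clean_dili_labs(), [], [], config)
        assert a1 == a2


class TestCohortCounts:
    def test_counting_and_nesting(self, config):
        assessments = []
        for i, labs_max in enumerate([300, 100, 25]):
            pid = f"p{i}"
            labs = [alt(-5, 20, pid), alt(30, labs_max, pid), alt(100, 15, pid)]
            assessments.append(assess_patient(era(pid=pid), labs, [], [], config))
        counts = compute_cohort_counts(assessments, config)["M1"]
        # p0 severe, p1 moderate, p2 no elevation -> eligible 3, ade 2
        assert (counts.n_eligible, counts.n_ade) == (3, 2)
        assert counts.n_ade_moderate_or_worse == 2
        assert counts.n_ade_severe == 1
        assert counts.n_ade_severe <= counts.n_ade_moderate_or_worse <= counts.n_ade

    def test_ineligible_patient_absent_from_denominator(self, config):
        a = assess_patient(era(), [alt(30, 300)], [], [], config)  # no baseline/after
        counts = compute_cohort_counts([a], config)["M1"]
        assert counts.n_eligible == 0 and counts.n_ade == 0

    def test_multi_era_patient_counts_once(self, config):
        labs = clean_dili_labs() + [alt(200, 18), alt(250, 19), alt(320, 17)]
        eras = [era(0, 90), era(240, 300)]
        assessments = [assess_patient(e, labs, [], [], config) for e in eras]
        counts = compute_cohort_counts(assessments, config)["M1"]
        assert counts.n_eligible == 1 and counts.n_ade == 1
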