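"""Patient classification and survival statistics on the packaged cohort."""

import numpy as np
import pytest

from conftest import naive_logrank_chi2

from vaccsig import (
    classify_clinical,
    classify_immunological,
    kaplan_meier,
    km_median_survival,
    logrank_test,
    pooled_median_survival,
    survival_summary,
)
from vaccsig.core import PatientRecord
from vaccsig.survival import group_records


def _rec(pid, months, died, dth="positive"):
    return PatientRecord(patient_id=pid, gender="NA", ajcc_stage="IV",
                         dth=dth, survival_months=months, died=died)


class TestImmunologicalClassification:
    def test_cohort_split_twelve_sixteen(self, patient_records):
        recs = classify_immunological(patient_records)
        groups = [r.immunological_group for r in recs]
        assert groups.count("responder") == 12
        assert groups.count("non_responder") == 16

    def test_never_tested_counts_as_non_responder(self):
        rec = classify_immunological([_rec("P", 5, True, dth="not_tested")])[0]
        assert rec.immunological_group == "non_responder"


class TestClinicalReclassification:
    def test_seven_responders_five_non_responders(self, classified_records):
        micro = [r for r in classified_records if r.microarray]
        labels = [r.clinical_group for r in micro]
        assert labels.count("responder") == 7
        assert labels.count("non_responder") == 5

    def test_short_surviving_dth_negative_is_non_responder(
            self, classified_records):
        by_id = {r.patient_id: r for r in classified_records}
        assert by_id["MT079"].clinical_group == "non_responder"  # 9 < 11
        assert by_id["MT083"].clinical_group == "responder"      # 17 > 11
        assert by_id["MT101"].clinical_group == "responder"      # 63.9 > 11

    def test_patients_off_the_array_stay_unassigned(self, classified_records):
        assert all(r.clinical_group == "unassigned"
                   for r in classified_records if not r.microarray)

    def test_infinite_threshold_reduces_to_dth_positive(self, patient_records):
        recs = classify_clinical(classify_immunological(patient_records),
                                 survival_threshold=1e9)
        micro = [r for r in recs if r.microarray]
        responders = {r.patient_id for r in micro
                      if r.clinical_group == "responder"}
        dth_pos = {r.patient_id for r in micro if r.dth == "positive"}
        assert responders == dth_pos

    def test_empty_profiled_set_rejected(self, patient_records):
        with pytest.raises(ValueError, match="empty"):
            classify_clinical(patient_records, microarray_ids=[])


class TestMedians:
    def test_pooled_medians_match_printed_cohort_values(self, patient_records):
        recs = classify_immunological(patient_records)
        resp = group_records(recs, "responder")
        non = group_records(recs, "non_responder")
        assert pooled_median_survival(resp) == pytest.approx(41.4)
        assert pooled_median_survival(non) == pytest.approx(9.85)

    def test_pooled_median_ignores_the_event_flag(self):
        a = [_rec(f"P{i}", m, True) for i, m in enumerate((1, 2, 3))]
        b = [_rec(f"P{i}", m, False) for i, m in enumerate((1, 2, 3))]
        assert pooled_median_survival(a) == pooled_median_survival(b) == 2.0

    def test_single_patient_group(self):
        assert pooled_median_survival([_rec("P", 7.3, True)]) == 7.3

    def test_km_median_differs_from_pooled_on_the_cohort(self, patient_records):
        # the responders' product-limit curve first crosses 0.5 at 35.1 months
        recs = classify_immunological(patient_records)
        resp = group_records(recs, "responder")
        assert km_median_survival(resp) == pytest.approx(35.1)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        months = [2.0, 5.0, 5.0, 9.0, 12.0]
        recs = [_rec(f"P{i}", m, True) for i, m in enumerate(months)]
        curve = kaplan_meier(recs).set_index("time")["survival"]
        assert curve.loc[2.0] == pytest.approx(4 / 5)
        assert curve.loc[5.0] == pytest.approx(2 / 5)
        assert curve.loc[12.0] == pytest.approx(0.0)

    def test_all_censored_stays_flat_at_one(self):
        recs = [_rec(f"P{i}", m, False) for i, m in enumerate((3.0, 8.0))]
        curve = kaplan_meier(recs)
        assert (curve["survival"] == 1.0).all()

    def test_censoring_shrinks_risk_set_without_step(self):
        # event at 2 (n=3), censor at 4, event at 6 with risk set of 1
        recs = [_rec("A", 2, True), _rec("B", 4, False), _rec("C", 6, True)]
        curve = kaplan_meier(recs).set_index("time")["survival"]
        assert curve.loc[2.0] == pytest.approx(2 / 3)
        assert curve.loc[4.0] == pytest.approx(2 / 3)
        assert curve.loc[6.0] == pytest.approx(0.0)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        months = (3.0, 7.0, 11.0, 20.0)
        a = [_rec(f"A{i}", m, True) for i, m in enumerate(months)]
        b = [_rec(f"B{i}", m, True) for i, m in enumerate(months)]
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_risk_set_computation(self):
        rng = np.random.default_rng(8)
        a = [_rec(f"A{i}", t, bool(d)) for i, (t, d) in enumerate(
            zip(rng.exponential(30, 15), rng.random(15) > 0.2))]
        b = [_rec(f"B{i}", t, bool(d)) for i, (t, d) in enumerate(
            zip(rng.exponential(12, 15), rng.random(15) > 0.2))]
        times = [r.survival_months for r in a + b]
        events = [r.died for r in a + b]
        labels = [True] * len(a) + [False] * len(b)
        for weights, wilcoxon in (("mantel_cox", False),
                                  ("gehan_breslow_wilcoxon", True)):
            chi2, _ = logrank_test(a, b, weights=weights)
            assert chi2 == pytest.approx(
                naive_logrank_chi2(times, events, labels, wilcoxon=wilcoxon),
                rel=1e-6)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(15)
        a = [_rec(f"A{i}", t, True) for i, t in
             enumerate(rng.exponential(25, 14))]
        b = [_rec(f"B{i}", t, True) for i, t in
             enumerate(rng.exponential(10, 14))]
        chi2, p = logrank_test(a, b)
        times = np.array([r.survival_months for r in a + b])
        events = np.array([r.died for r in a + b])
        labels = np.array([True] * 14 + [False] * 14)
        perm = np.random.default_rng(0)
        exceed = 0
        n_perm = 2000
        for _ in range(n_perm):
            exceed += naive_logrank_chi2(times, events,
                                         perm.permutation(labels)) >= chi2
        assert abs(exceed / n_perm - p) < 0.05

    def test_single_event_time_makes_weightings_agree(self):
        # with one distinct event time every risk set has the same size,
        # so the at-risk weighting cancels out of the statistic
        a = [_rec("A1", 5, True), _rec("A2", 5, True), _rec("A3", 9, False)]
        b = [_rec("B1", 5, True), _rec("B2", 9, False), _rec("B3", 9, False)]
        mc, _ = logrank_test(a, b)
        gbw, _ = logrank_test(a, b, weights="gehan_breslow_wilcoxon")
        assert mc == pytest.approx(gbw)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test([], [_rec("B", 5, True)])


class TestSummary:
    def test_cohort_summary_bundle(self, patient_records):
        recs = classify_immunological(patient_records)
        s = survival_summary(recs)
        assert s.group_sizes == {"responder": 12, "non_responder": 16}
        assert s.pooled_medians["responder"] == pytest.approx(41.4)
        assert s.alive_fractions["non_responder"] == pytest.approx(0.125)
        assert s.logrank_p < 0.05 and s.gbw_p < 0.05
        for curve in s.km_curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] <= 1.0 and (np.diff(surv) <= 1e-12).all()
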