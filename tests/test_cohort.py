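"""Cohort builder: inclusion criteria, follow-up windows, filter log."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from lotline import (
    CohortCriteria,
    CoverageInterval,
    DiagnosisEvent,
    DrugClaim,
    build_cohort,
    determine_followup_end,
)
from lotline.records import CohortMember, months_between
from conftest import day, make_patient


def _rx(D, start_day: int, n_fills: int = 6):
    return [DrugClaim(D(start_day + 30 * i), "lenalidomide", 30) for i in range(n_fills)]


class TestFollowupEnd:
    def test_claims_source_ends_with_coverage(self):
        p = make_patient(index=date(2010, 6, 1),
                         coverage_start=date(2009, 1, 1), coverage_end=date(2013, 6, 30))
        assert determine_followup_end(p, date(2010, 6, 1)) == date(2013, 6, 30)

    def test_emr_source_ends_at_last_activity(self):
        p = make_patient(index=date(2010, 6, 1), source_kind="emr",
                         claims=[DrugClaim(date(2015, 2, 10), "lenalidomide", 30)])
        assert determine_followup_end(p, date(2010, 6, 1)) == date(2015, 2, 10)

    def test_death_truncates_followup(self):
        p = make_patient(index=date(2010, 6, 1), death=date(2012, 1, 1),
                         coverage_start=date(2009, 1, 1), coverage_end=date(2013, 6, 30))
        assert determine_followup_end(p, date(2010, 6, 1)) == date(2012, 1, 1)

    def test_no_coverage_at_index_signals_ineligibility(self):
        p = make_patient(index=date(2010, 6, 1),
                         coverage_start=date(2009, 1, 1), coverage_end=date(2010, 1, 1))
        assert determine_followup_end(p, date(2010, 6, 1)) is None

    def test_bridgeable_coverage_gap_extends_followup(self):
        p = make_patient(index=date(2010, 6, 1))
        p.coverage = [
            CoverageInterval(date(2009, 1, 1), date(2011, 1, 1), "medical"),
            CoverageInterval(date(2011, 1, 20), date(2013, 1, 1), "medical"),
            CoverageInterval(date(2009, 1, 1), date(2013, 1, 1), "pharmacy"),
        ]
        assert determine_followup_end(p, date(2010, 6, 1), coverage_gap_days=0) == date(2011, 1, 1)
        assert determine_followup_end(p, date(2010, 6, 1), coverage_gap_days=30) == date(2013, 1, 1)


class TestFollowupMonths:
    @pytest.mark.parametrize("days,expected", [(0, 0.0), (365, 11.99), (546, 17.94)])
    def test_day_to_month_conversion(self, days, expected):
        start = date(2010, 1, 1)
        m = CohortMember("p", start, 70, "65-74", "male", "white", "non_transplant",
                         start + timedelta(days=days))
        from lotline import followup_months
        assert followup_months(m, start) == pytest.approx(expected, abs=0.01)

    def test_specific_calendar_span(self):
        # 546 days between these dates: 546 / 30.4375 = 17.94
        assert months_between(date(2010, 1, 1), date(2011, 7, 1)) == pytest.approx(546 / 30.4375)


class TestBuildCohort:
    def test_index_before_floor_excluded_at_first_criterion(self):
        p = make_patient(index=date(2006, 12, 31), claims=_rx(day, 0))
        result = build_cohort([p])
        assert result.filter_log.steps[0].n_excluded == 1
        assert not result.members

    def test_index_on_floor_included(self):
        idx = date(2007, 1, 1)
        p = make_patient(index=idx, claims=[DrugClaim(idx + timedelta(days=10 + 30 * i),
                                                      "lenalidomide", 30) for i in range(4)])
        result = build_cohort([p])
        assert len(result.members) == 1

    def test_prior_malignancy_within_lookback_excluded(self):
        idx = date(2010, 6, 1)
        p = make_patient(
            index=idx, claims=_rx(day, 200),
            extra_diagnoses=[DiagnosisEvent(idx - timedelta(days=100), "C80.1")])
        result = build_cohort([p])
        step = {s.criterion: s for s in result.filter_log.steps}["no_prior_malignancy"]
        assert step.n_excluded == 1

    def test_prior_malignancy_outside_lookback_kept(self):
        idx = date(2010, 6, 1)
        p = make_patient(
            index=idx,
            claims=[DrugClaim(idx + timedelta(days=30 * i), "lenalidomide", 30) for i in range(4)],
            extra_diagnoses=[DiagnosisEvent(idx - timedelta(days=400), "C80.1")])
        assert len(build_cohort([p]).members) == 1

    def test_planted_violations_tallied_per_criterion(self):
        """Each planted defect is removed at exactly the intended step."""
        idx = date(2010, 6, 1)
        rx = [DrugClaim(idx + timedelta(days=30 * i), "lenalidomide", 30) for i in range(4)]
        clean = [make_patient(pid=f"ok{i}", index=idx, claims=list(rx)) for i in range(4)]
        early = [make_patient(pid="early", index=date(2006, 6, 1),
                              claims=[DrugClaim(date(2006, 7, 1), "lenalidomide", 30)])]
        nosex = [make_patient(pid="nosex", index=idx, claims=list(rx), sex=None)]
        nocov = [make_patient(pid="nocov", index=idx, claims=list(rx),
                              coverage_start=idx + timedelta(days=30),
                              coverage_end=idx + timedelta(days=400))]
        shortlb = [make_patient(pid="shortlb", index=idx, claims=list(rx),
                                coverage_start=idx - timedelta(days=100))]
        prior = [make_patient(pid="prior", index=idx, claims=list(rx),
                              extra_diagnoses=[DiagnosisEvent(idx - timedelta(days=50), "C80.1")])]
        untreated = [make_patient(pid="untreated", index=idx)]
        pop = clean + early + nosex + nocov + shortlb + prior + untreated
        result = build_cohort(pop)
        excluded = {s.criterion: s.n_excluded for s in result.filter_log.steps}
        assert excluded == {
            "index_on_or_after_floor": 1,
            "known_sex": 1,
            "coverage_active_at_index": 1,
            "lookback_coverage": 1,
            "no_prior_malignancy": 1,
            "received_at_least_one_lot": 1,
        }
        assert {m.patient_id for m in result.members} == {f"ok{i}" for i in range(4)}

    def test_filter_log_chains_and_is_monotone(self, small_population):
        log = build_cohort(small_population).filter_log
        sizes = [log.steps[0].n_before] + [s.n_after for s in log.steps]
        assert sizes == sorted(sizes, reverse=True)
        for a, b in zip(log.steps, log.steps[1:]):
            assert a.n_after == b.n_before

    def test_included_members_pass_criteria_on_recheck(self, small_population):
        """Idempotence: re-filtering the included members excludes nobody."""
        result = build_cohort(small_population)
        kept = {m.patient_id for m in result.members}
        sub = [p for p in small_population if p.patient_id in kept]
        again = build_cohort(sub)
        assert {m.patient_id for m in again.members} == kept
        assert all(s.n_excluded == 0 for s in again.filter_log.steps)

    def test_transplant_stratum_requires_asct_in_followup(self, small_population):
        result = build_cohort(small_population)
        truth = {p.patient_id: p.truth["stratum"] for p in small_population}
        for m in result.members:
            assert m.transplant_status == truth[m.patient_id]

    def test_age_is_index_year_minus_birth_year(self):
        p = make_patient(index=date(2010, 6, 1), birth_year=1940,
                         claims=[DrugClaim(date(2010, 7, 1), "lenalidomide", 30)])
        m = build_cohort([p]).members[0]
        assert m.age_at_diagnosis == 70
        assert m.age_category == "65-74"
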