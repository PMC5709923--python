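"""Closed-form estimators: worked-example values, bounds, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptfr import (
    NEVER_EVENT,
    OracleMissingError,
    Status,
    SubjectRecord,
    UndefinedRateError,
    VisitHistory,
    cci_rate,
    observed_pt_irregular,
    percentage_rate,
    ptfr_lower_bound,
    spt_rate,
    true_ptfr,
)
from ptfr.datasets import toy_cohort

from .conftest import random_oracle_cohort

TAU = 3.0


class TestWorkedExamples:
    """The 100-subject annual-visit cohort, checked against hand bookkeeping.

    Observed person-time is 165 py (A) / 245 py (B); potential person-time
    with dropouts followed to the horizon is 265 py; N*tau = 300 py.
    """

    def test_percentage_blind_to_dropout_timing(self, toy_a, toy_b):
        assert percentage_rate(toy_a, TAU) == 60.0
        assert percentage_rate(toy_b, TAU) == 60.0

    def test_cci(self, toy_a, toy_b):
        assert cci_rate(toy_a, TAU) == pytest.approx(100 * 165 / 265)
        assert cci_rate(toy_b, TAU) == pytest.approx(100 * 245 / 265)
        assert round(cci_rate(toy_a, TAU), 1) == 62.3
        assert round(cci_rate(toy_b, TAU), 1) == 92.5

    def test_spt(self, toy_a, toy_b):
        assert spt_rate(toy_a, TAU) == pytest.approx(100 * 200 / 300)
        assert spt_rate(toy_b, TAU) == pytest.approx(100 * 280 / 300)

    def test_true_ptfr_equals_cci_when_no_dropout_events(self, toy_a, toy_b):
        assert true_ptfr(toy_a, TAU) == pytest.approx(cci_rate(toy_a, TAU))
        assert true_ptfr(toy_b, TAU) == pytest.approx(cci_rate(toy_b, TAU))

    def test_true_ptfr_with_dropout_events(self, toy_a_events):
        # 5 dropouts event at 0.5 y: denominator shrinks from 265 to 252.5
        assert true_ptfr(toy_a_events, TAU) == pytest.approx(100 * 165 / 252.5)
        assert round(true_ptfr(toy_a_events, TAU), 1) == 65.3

    def test_lower_bound_is_cci(self, toy_a, toy_b):
        assert ptfr_lower_bound(toy_a, TAU) == cci_rate(toy_a, TAU)
        assert ptfr_lower_bound(toy_b, TAU) == cci_rate(toy_b, TAU)


class TestDegenerateCohorts:
    def _cohort(self, statuses, times, tau=TAU):
        return [
            SubjectRecord(str(i), t, s, NEVER_EVENT if s is not Status.EVENT else t)
            for i, (s, t) in enumerate(zip(statuses, times))
        ]

    def test_no_dropouts_all_rates_100(self):
        cohort = self._cohort(
            [Status.EVENT, Status.ADMIN_CENSORED], [1.0, TAU]
        )
        for rate in (percentage_rate, cci_rate, spt_rate, true_ptfr):
            assert rate(cohort, TAU) == 100.0

    def test_all_dropouts_percentage_zero(self):
        cohort = self._cohort([Status.DROPOUT] * 3, [0.5, 1.0, 1.5])
        assert percentage_rate(cohort, TAU) == 0.0

    def test_single_dropout_halfway_spt(self):
        cohort = self._cohort([Status.DROPOUT], [TAU / 2])
        assert spt_rate(cohort, TAU) == 50.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(UndefinedRateError):
            percentage_rate([], TAU)
        with pytest.raises(UndefinedRateError):
            cci_rate([], TAU)

    def test_dropout_without_oracle_rejected(self):
        cohort = [SubjectRecord("a", 1.0, Status.DROPOUT)]
        with pytest.raises(OracleMissingError):
            true_ptfr(cohort, TAU)


class TestOrderingAndInvariance:
    def test_cci_never_exceeds_true_rate_or_spt(self):
        # both lower bounds are algebraic identities, valid for any cohort
        rng = np.random.default_rng(2024)
        for _ in range(300):
            cohort = random_oracle_cohort(rng)
            tau = 5.0
            lo = cci_rate(cohort, tau)
            assert lo <= true_ptfr(cohort, tau) + 1e-9
            assert lo <= spt_rate(cohort, tau) + 1e-9

    def test_spt_upper_bound_exact_when_dropouts_event_free(self):
        # with every dropout event-free through tau the true rate collapses
        # onto the completeness index, and CCI <= SPT always holds
        rng = np.random.default_rng(2025)
        for _ in range(200):
            cohort = [
                SubjectRecord(
                    r.subject_id, r.exit_time, r.status,
                    NEVER_EVENT if r.status is Status.DROPOUT else r.true_event_time,
                )
                for r in random_oracle_cohort(rng)
            ]
            mid = true_ptfr(cohort, 5.0)
            assert cci_rate(cohort, 5.0) == pytest.approx(mid)
            assert mid <= spt_rate(cohort, 5.0) + 1e-9

    def test_spt_upper_bound_has_counterexamples(self):
        # a dropout whose counterfactual event falls soon after dropping out
        # keeps most of its no-dropout person-time, so the true rate can
        # exceed the SPT: here 50% vs 20%
        cohort = [SubjectRecord("a", 1.0, Status.DROPOUT, true_event_time=2.0)]
        assert true_ptfr(cohort, 5.0) == 50.0
        assert spt_rate(cohort, 5.0) == 20.0

    def test_rates_invariant_to_subject_order(self):
        rng = np.random.default_rng(5)
        cohort = random_oracle_cohort(rng, n=40)
        shuffled = list(cohort)
        rng.shuffle(shuffled)
        for rate in (percentage_rate, cci_rate, spt_rate, true_ptfr):
            assert rate(shuffled, 5.0) == pytest.approx(rate(cohort, 5.0))

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_rates_invariant_to_time_rescaling(self, scale):
        rng = np.random.default_rng(17)
        cohort = random_oracle_cohort(rng, n=30)
        scaled = [
            SubjectRecord(
                r.subject_id,
                r.exit_time * scale,
                r.status,
                None if r.true_event_time is None else r.true_event_time * scale,
            )
            for r in cohort
        ]
        for rate in (percentage_rate, cci_rate, spt_rate, true_ptfr):
            assert rate(scaled, 5.0 * scale) == pytest.approx(rate(cohort, 5.0))

    def test_percentage_ignores_dropout_timing_but_spt_does_not(self):
        early = toy_cohort("A")
        late = toy_cohort("B")
        assert percentage_rate(early, TAU) == percentage_rate(late, TAU)
        assert spt_rate(early, TAU) != spt_rate(late, TAU)


class TestIrregularObservedPt:
    def test_event_contributes_final_gap_midpoint(self):
        h = VisitHistory("a", (0.0, 1.0, 2.4), event_at_last_visit=True)
        assert observed_pt_irregular([h], 3.0) == pytest.approx(1.7)

    def test_censored_contributes_last_visit(self):
        h = VisitHistory("a", (0.0, 2.0), event_at_last_visit=False)
        assert observed_pt_irregular([h], 3.0) == pytest.approx(2.0)

    def test_contribution_capped_at_target(self):
        h = VisitHistory("a", (0.0, 4.0), event_at_last_visit=False)
        assert observed_pt_irregular([h], 3.0) == pytest.approx(3.0)

    def test_empty_history_list_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert observed_pt_irregular([], 3.0) == 0.0
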