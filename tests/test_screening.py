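"""Classification, referral cascade, schedules, and screening events."""

import numpy as np
import pytest

from drscreen.markov_engine import initial_distribution, run_cohort
from drscreen.screening import (
    ScreeningPolicy,
    apply_screening_event,
    classification_matrix,
    referral_probabilities,
    schedule,
)
from drscreen.states import (
    DME_TX,
    DME_U,
    NO_DR,
    NPDR_DX,
    NPDR_U,
    N_STATES,
    PDR_TX,
    PDR_U,
)


def _perfect_test(params, modality="community"):
    t = params.tests[modality]
    t.normal_called_npdr.base = 0.0
    t.normal_called_normal.base = 1.0
    t.npdr_called_normal.base = 0.0
    t.pdr_called_npdr.base = 0.0
    t.pdr_called_normal.base = 0.0
    t.dme_sensitivity.base = 1.0
    t.dme_specificity.base = 1.0
    return params


class TestClassificationMatrix:
    def test_community_fixture_rows(self, rural_params):
        cm = classification_matrix(rural_params.tests["community"])
        assert cm.grades.loc["no_dr", "called_npdr"] == 0.05
        assert cm.grades.loc["no_dr", "called_normal"] == pytest.approx(0.95)
        assert cm.grades.loc["pdr", "called_pdr"] == pytest.approx(1 - 0.03 - 0.02)
        assert cm.dme_positive["dme"] == 0.82
        assert cm.dme_positive["no_dr"] == pytest.approx(1 - 0.79)

    def test_rows_sum_to_one(self, rural_params, urban_params):
        for params in (rural_params, urban_params):
            for modality in ("community", "telemedicine"):
                cm = classification_matrix(params.tests[modality])
                assert np.abs(cm.grades.sum(axis=1) - 1.0).max() < 1e-12

    def test_perfect_test_is_identity(self, rural_params):
        cm = classification_matrix(_perfect_test(rural_params).tests["community"])
        assert cm.grades.loc["no_dr", "called_normal"] == 1.0
        assert cm.grades.loc["npdr", "called_npdr"] == 1.0
        assert cm.grades.loc["pdr", "called_pdr"] == 1.0
        assert cm.dme_positive["dme"] == 1.0
        assert cm.dme_positive["no_dr"] == 0.0


class TestSchedule:
    def test_one_off_only_first_cycle(self):
        policy = ScreeningPolicy("community")
        assert schedule(policy, 0) is True
        assert all(not schedule(policy, c) for c in range(1, 10))

    def test_every_two_years(self):
        policy = ScreeningPolicy("community", 2)
        assert [schedule(policy, c) for c in range(6)] == [True, False] * 3

    def test_every_three_years_cycle_nine(self):
        assert schedule(ScreeningPolicy("telemedicine", 3), 9) is True

    def test_no_screening_never(self):
        assert not any(schedule(ScreeningPolicy("none"), c) for c in range(30))

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            schedule(ScreeningPolicy("community"), -1)


class TestApplyScreeningEvent:
    def test_healthy_cohort_pays_screening_and_false_positive_exams(self, rural_params):
        occ = np.zeros(N_STATES)
        occ[NO_DR] = 1.0
        policy = ScreeningPolicy("community")
        new, cost = apply_screening_event(occ, policy, rural_params)
        uptake, accept = 0.80, 0.70
        referred = uptake * 0.05 * accept
        expected = uptake * rural_params.costs.screening_per_person["community"].base
        expected += referred * 100.0
        assert cost == pytest.approx(expected, abs=1e-9)
        assert (new == occ).all()  # false positives keep their state

    def test_zero_uptake_is_a_no_op(self, rural_params):
        occ = initial_distribution(rural_params)
        policy = ScreeningPolicy("community", uptake=0.0)
        new, cost = apply_screening_event(occ, policy, rural_params)
        assert cost == 0.0
        assert (new == occ).all()

    def test_pdr_cohort_perfect_cascade(self, rural_params):
        params = _perfect_test(rural_params)
        occ = np.zeros(N_STATES)
        occ[PDR_U] = 1.0
        policy = ScreeningPolicy("community", uptake=1.0, referral_acceptance=1.0)
        new, cost = apply_screening_event(occ, policy, params)
        assert new[PDR_TX] == pytest.approx(1.0)
        expected = (
            params.costs.screening_per_person["community"].base + 100.0 + 137.60
        )
        assert cost == pytest.approx(expected, abs=1e-9)

    def test_mass_conserved_and_flags_updated(self, rural_params):
        occ = initial_distribution(rural_params)
        policy = ScreeningPolicy("telemedicine")
        new, cost = apply_screening_event(occ, policy, rural_params)
        assert new.sum() == pytest.approx(occ.sum(), abs=1e-12)
        assert cost > 0
        # detection moves mass within a health state, never across
        for u_state, m_state in ((NPDR_U, NPDR_DX), (PDR_U, PDR_TX), (DME_U, DME_TX)):
            assert new[u_state] + new[m_state] == pytest.approx(
                occ[u_state] + occ[m_state], abs=1e-12
            )

    def test_dme_false_positive_referrals_add_exam_costs(self, rural_params):
        occ = np.zeros(N_STATES)
        occ[NO_DR] = 1.0
        base = apply_screening_event(occ, ScreeningPolicy("community"), rural_params)[1]
        rural_params.options.dme_false_positive_referrals = True
        layered = apply_screening_event(occ, ScreeningPolicy("community"), rural_params)[1]
        assert layered > base

    def test_referral_probabilities_default_mode(self, rural_params):
        r = referral_probabilities(ScreeningPolicy("community"), rural_params)
        assert r[NO_DR] == pytest.approx(0.05)
        assert r[NPDR_U] == pytest.approx(1 - 0.22)
        assert r[PDR_U] == pytest.approx(1 - 0.02)
        assert r[DME_U] == pytest.approx(0.82)
        assert r[NPDR_DX] == 0.0  # already under care


def test_perfect_screening_cannot_reduce_health(rural_params):
    """With a perfect test and full compliance, screening adds QALYs."""
    params = _perfect_test(rural_params)
    policy = ScreeningPolicy("community", uptake=1.0, referral_acceptance=1.0)
    _, screened = run_cohort(params, policy)
    _, unscreened = run_cohort(params, ScreeningPolicy("none"))
    assert screened.qalys_per_person >= unscreened.qalys_per_person


def test_policy_validation():
    with pytest.raises(ValueError):
        ScreeningPolicy("mail-order")
    with pytest.raises(ValueError):
        ScreeningPolicy("community", 0)
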