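"""Cohort engine: matrices, mortality, mass conservation, discounting."""

import numpy as np
import pytest

from drscreen.markov_engine import (
    build_transition_matrix,
    cycle_mortality,
    initial_distribution,
    run_cohort,
    utility_vector,
)
from drscreen.screening import ScreeningPolicy
from drscreen.states import (
    DEATH,
    DME_U,
    HealthState,
    NO_DR,
    NPDR_U,
    N_STATES,
    PDR_TX,
    PDR_U,
    SVI_NEW,
)


def _degenerate(params, utility=1.0, discount=0.0, n_cycles=10):
    """Single-state world: no disease, no mortality, flat utility."""
    p = params.copy()
    for name in (
        "npdr", "pdr", "dme",
    ):
        getattr(p.prevalence, name).base = 0.0
    for name in p.transitions.__dataclass_fields__:
        getattr(p.transitions, name).base = 0.0
    p.mortality.q = np.zeros_like(p.mortality.q)
    p.utilities.no_dr.base = utility
    p.economics.discount_rate = discount
    p.economics.n_cycles = n_cycles
    return p


class TestInitialDistribution:
    def test_rural_fixture(self, rural_params):
        occ = initial_distribution(rural_params)
        assert occ[NO_DR] == pytest.approx(1 - 0.256 - 0.016 - 0.035, abs=1e-12)
        assert occ[NPDR_U] == 0.256
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)

    def test_urban_fixture(self, urban_params):
        assert initial_distribution(urban_params)[NPDR_U] == 0.149

    def test_zero_prevalence_all_healthy(self, rural_params):
        for k in ("npdr", "pdr", "dme"):
            getattr(rural_params.prevalence, k).base = 0.0
        occ = initial_distribution(rural_params)
        assert occ[NO_DR] == 1.0

    def test_prevalence_overflow_rejected(self, rural_params):
        rural_params.prevalence.npdr.base = 0.99
        with pytest.raises(ValueError):
            initial_distribution(rural_params)


class TestCycleMortality:
    def test_diabetes_multiplier(self, rural_params):
        # q(50) = 0.004 on the synthetic schedule
        q = cycle_mortality(50, HealthState.NPDR, rural_params.mortality)
        assert q == pytest.approx(0.004 * 1.97, abs=1e-12)

    def test_svi_multiplier_replaces(self, rural_params):
        q = cycle_mortality(50, HealthState.SVI, rural_params.mortality)
        assert q == pytest.approx(0.004 * 3.9, abs=1e-12)

    def test_svi_multiplier_can_stack(self, rural_params):
        rural_params.mortality.svi_multiplier_mode = "multiply"
        q = cycle_mortality(50, HealthState.SVI, rural_params.mortality)
        assert q == pytest.approx(0.004 * 3.9 * 1.97, abs=1e-12)

    def test_capped_at_one(self, rural_params):
        rural_params.mortality.q[:] = 0.9
        assert cycle_mortality(60, HealthState.SVI, rural_params.mortality) == 1.0

    def test_extrapolates_beyond_schedule(self, rural_params):
        last = rural_params.mortality.q[-1]
        q = cycle_mortality(200, HealthState.NO_DR, rural_params.mortality)
        assert q == min(1.0, last * 1.97)

    def test_below_schedule_rejected(self, rural_params):
        with pytest.raises(ValueError):
            cycle_mortality(30, HealthState.NO_DR, rural_params.mortality)


class TestTransitionMatrix:
    @pytest.mark.parametrize("setting_fixture", ["rural_params", "urban_params"])
    @pytest.mark.parametrize("age", [50, 65, 80, 120])
    def test_rows_are_stochastic(self, setting_fixture, age, request):
        params = request.getfixturevalue(setting_fixture)
        M = build_transition_matrix(params, age)
        assert np.all(M >= 0) and np.all(M <= 1)
        assert np.abs(M.sum(axis=1) - 1.0).max() < 1e-12

    def test_no_dr_row_uses_fixture_probabilities(self, rural_params):
        rural_params.mortality.q = np.zeros_like(rural_params.mortality.q)
        M = build_transition_matrix(rural_params, 50)
        assert M[NO_DR, NPDR_U] == pytest.approx(0.0328, abs=1e-12)
        assert M[NO_DR, PDR_U] == pytest.approx(0.0024, abs=1e-12)
        assert M[NO_DR, NO_DR] == pytest.approx(1 - 0.0328 - 0.0024, abs=1e-12)

    def test_treated_pdr_progresses_more_slowly(self, rural_params):
        rural_params.mortality.q = np.zeros_like(rural_params.mortality.q)
        M = build_transition_matrix(rural_params, 50)
        assert M[PDR_TX, SVI_NEW] == pytest.approx(0.0116, abs=1e-12)
        assert M[PDR_U, SVI_NEW] == pytest.approx(0.0278, abs=1e-12)

    def test_death_is_absorbing(self, rural_params):
        M = build_transition_matrix(rural_params, 70)
        expected = np.zeros(N_STATES)
        expected[DEATH] = 1.0
        assert (M[DEATH] == expected).all()

    def test_degenerate_model_is_identity_up_to_svi_ageing(self, rural_params):
        p = _degenerate(rural_params)
        expected = np.eye(N_STATES)
        # first-year SVI always ages into established SVI (bookkeeping row)
        expected[SVI_NEW, SVI_NEW] = 0.0
        expected[SVI_NEW, SVI_NEW + 1] = 1.0
        assert (build_transition_matrix(p, 55) == expected).all()


class TestRunCohort:
    def test_constant_occupancy_undiscounted_qalys(self, rural_params):
        p = _degenerate(rural_params, utility=1.0, discount=0.0, n_cycles=10)
        _, res = run_cohort(p, ScreeningPolicy("none"))
        assert res.qalys_per_person == pytest.approx(10.0, abs=1e-12)
        assert res.cost_per_person == 0.0

    def test_discounted_qalys_match_geometric_sum(self, rural_params):
        u, d, T = 0.8, 0.05, 12
        p = _degenerate(rural_params, utility=u, discount=d, n_cycles=T)
        _, res = run_cohort(p, ScreeningPolicy("none"))
        oracle = u * sum((1 + d) ** -t for t in range(1, T + 1))
        assert res.qalys_per_person == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize(
        "policy",
        [
            ScreeningPolicy("none"),
            ScreeningPolicy("community"),
            ScreeningPolicy("telemedicine", 2),
            ScreeningPolicy("community", 1),
        ],
    )
    def test_mass_conserved_every_cycle(self, rural_params, policy):
        trace, _ = run_cohort(rural_params, policy)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-12
        assert (trace.occupancy >= 0).all()

    def test_discounting_reduces_totals(self, rural_params):
        undiscounted = rural_params.copy()
        undiscounted.economics.discount_rate = 0.0
        for policy in (ScreeningPolicy("none"), ScreeningPolicy("community")):
            _, r0 = run_cohort(undiscounted, policy)
            _, r35 = run_cohort(rural_params, policy)
            assert r0.qalys_per_person > r35.qalys_per_person
            assert r0.cost_per_person > r35.cost_per_person

    def test_cumulative_totals_nondecreasing(self, rural_params):
        trace, _ = run_cohort(rural_params, ScreeningPolicy("community"))
        assert (np.diff(trace.disc_cost_cum) >= -1e-12).all()
        assert (np.diff(trace.disc_qaly_cum) >= -1e-12).all()

    def test_screening_without_treatment_effect_adds_no_health(self, rural_params):
        """Zeroing the treatment effect makes screening health-neutral.

        Treated rates are set equal to untreated ones and treated PDR regains
        the DME-progression path, so detection changes costs but not disease
        dynamics; screened QALYs must not exceed unscreened QALYs.
        """
        p = rural_params
        p.transitions.treated_pdr_to_svi.base = p.transitions.pdr_to_svi.base
        p.transitions.treated_dme_to_svi.base = p.transitions.dme_to_svi.base
        p.options.treated_pdr_to_dme = True
        _, none = run_cohort(p, ScreeningPolicy("none"))
        for strategy in ("community", "telemedicine"):
            _, screened = run_cohort(p, ScreeningPolicy(strategy))
            assert screened.qalys_per_person <= none.qalys_per_person + 1e-9
            assert screened.cost_per_person > none.cost_per_person

    def test_trace_export_shape(self, rural_params):
        trace, _ = run_cohort(rural_params, ScreeningPolicy("community"))
        df = trace.to_frame()
        assert len(df) == rural_params.economics.n_cycles
        assert {"cycle", "age", "cost", "qaly", "disc_cost_cum"} <= set(df.columns)

    def test_utility_vector_maps_health_states(self, rural_params):
        u = utility_vector(rural_params)
        assert u[DEATH] == 0.0
        assert u[NO_DR] == 0.95
        assert u[DME_U] == u[PDR_U] == 0.70
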