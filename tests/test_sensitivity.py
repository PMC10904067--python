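"""Distribution fitting, one-way DSA behaviour, and PSA invariants."""

import numpy as np
import pytest

from drscreen.screening import ScreeningPolicy
from drscreen.sensitivity import (
    DistributionFitError,
    fit_all_distributions,
    fit_distribution,
    one_way_dsa,
    run_psa,
    tornado_table,
)


class TestFitDistribution:
    def test_symmetric_beta(self):
        d = fit_distribution(0.5, 0.4, 0.6, "beta")
        a, b = d.shape
        assert a == pytest.approx(b)
        assert d.mean() == pytest.approx(0.5)

    def test_utility_beta_moments(self):
        d = fit_distribution(0.95, 0.92, 0.99, "beta")
        assert d.mean() == pytest.approx(0.95, rel=1e-12)
        a, b = d.shape
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx((0.99 - 0.92) / (2 * 1.959964), rel=1e-9)

    def test_cost_gamma_moments(self):
        d = fit_distribution(100.0, 80.0, 120.0, "gamma")
        k, theta = d.shape
        assert k * theta == pytest.approx(100.0)
        assert k * theta**2 == pytest.approx(((120 - 80) / (2 * 1.959964)) ** 2)

    def test_zero_width_interval_is_fixed(self):
        d = fit_distribution(1.97, 1.97, 1.97, "beta")
        assert d.family == "fixed"
        assert d.sample(np.random.default_rng(0)) == 1.97

    def test_impossible_beta_variance_rejected(self):
        with pytest.raises(DistributionFitError, match="variance"):
            fit_distribution(0.05, 0.0, 0.9, "beta")

    def test_base_outside_interval_rejected(self):
        with pytest.raises(DistributionFitError):
            fit_distribution(0.5, 0.6, 0.9, "beta")

    @pytest.mark.parametrize(
        "base,lo,hi,family",
        [
            (0.95, 0.92, 0.99, "beta"),
            (0.0278, 0.0100, 0.0744, "beta"),
            (1741.46, 870.73, 2612.19, "gamma"),
        ],
    )
    def test_monte_carlo_mean_matches_base(self, base, lo, hi, family):
        d = fit_distribution(base, lo, hi, family)
        draws = d.sample(np.random.default_rng(20240101), size=100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - base) < 3 * se

    def test_every_fixture_parameter_fits(self, rural_params, urban_params):
        for params in (rural_params, urban_params):
            fits = fit_all_distributions(params)
            for ref, dist in fits:
                assert dist.mean() == pytest.approx(ref.get(params).base, rel=1e-6)


@pytest.fixture(scope="module")
def entries():
    from drscreen import load_parameters

    params = load_parameters(setting="rural")
    return one_way_dsa(params, ScreeningPolicy("community"), ScreeningPolicy("none"))


class TestOneWayDsa:
    def test_sorted_by_span(self, entries):
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_inputs_stay_in_support(self, entries):
        for e in entries:
            if "cost" in e.name or e.name.startswith("costs"):
                assert e.low_input >= 0
            if e.name.startswith(("prevalence", "transitions", "utilities", "tests", "compliance")):
                assert 0.0 <= e.low_input <= e.high_input <= 1.0

    def test_irrelevant_parameter_has_zero_span(self, entries):
        # telemedicine test accuracy cannot move a community-vs-none ICUR
        by_name = {e.name: e for e in entries}
        assert by_name["tests.telemedicine.dme_sensitivity"].span == 0.0

    def test_relevant_parameter_has_positive_span(self, entries):
        by_name = {e.name: e for e in entries}
        assert by_name["transitions.treated_pdr_to_svi"].span > 0.0
        assert by_name["compliance.uptake"].span > 0.0

    def test_table_export(self, entries):
        df = tornado_table(entries)
        assert list(df["parameter"]) == [e.name for e in entries]
        assert (df["span"] >= 0).all()


class TestRunPsa:
    def _policies(self):
        return [ScreeningPolicy("none"), ScreeningPolicy("community")]

    def test_seed_determinism(self, rural_params):
        a = run_psa(rural_params, self._policies(), n_iter=15, seed=11)
        b = run_psa(rural_params, self._policies(), n_iter=15, seed=11)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        s_a = a.comparisons["community_oneoff_vs_none"]
        s_b = b.comparisons["community_oneoff_vs_none"]
        assert np.array_equal(s_a.ceac, s_b.ceac)
        assert s_a.icur_ci == s_b.icur_ci

    def test_different_seeds_differ(self, rural_params):
        a = run_psa(rural_params, self._policies(), n_iter=10, seed=1)
        b = run_psa(rural_params, self._policies(), n_iter=10, seed=2)
        assert not np.array_equal(a.costs, b.costs)

    def test_ceac_monotone_when_qaly_gain_certain(self, rural_params):
        res = run_psa(rural_params, self._policies(), n_iter=60, seed=5)
        s = res.comparisons["community_oneoff_vs_none"]
        gain = s.delta_qaly > 0
        ceac = [np.mean(lam * s.delta_qaly[gain] - s.delta_cost[gain] > 0) for lam in s.lambdas]
        assert (np.diff(ceac) >= 0).all()

    def test_minimum_iterations_enforced(self, rural_params):
        with pytest.raises(ValueError):
            run_psa(rural_params, self._policies(), n_iter=1, seed=0)

    def test_draw_export(self, rural_params):
        res = run_psa(rural_params, self._policies(), n_iter=5, seed=0, keep_draws=True)
        assert len(res.draws) == 5
        assert "transitions.treated_pdr_to_svi" in res.draws.columns
        # fixed parameters never move
        assert res.draws["mortality.rr_svi"].nunique() == 1
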