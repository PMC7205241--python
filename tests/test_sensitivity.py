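"""Moment-matched samplers, probabilistic SA, CEAC, and tornado analysis."""

import math

import numpy as np
import pandas as pd
import pytest

import psmcea as m
from psmcea import sensitivity as sens


@pytest.fixture(scope="module")
def psa(bundle):
    return m.run_psa(bundle, n=400, seed=7)


class TestMakeDistribution:
    def test_beta_moment_matching_algebra(self):
        # m = 0.68, s = 0.068 -> nu = m(1-m)/s^2 - 1, alpha = m nu, beta = (1-m) nu
        nu = 0.68 * 0.32 / 0.068**2 - 1
        assert 0.68 * nu == pytest.approx(31.32, abs=0.01)
        assert 0.32 * nu == pytest.approx(14.74, abs=0.01)
        spec = m.ParamDistribution("utility_pfs", "beta", 0.68)
        draws = m.make_distribution(spec)(np.random.default_rng(0), 20000)
        assert draws.mean() == pytest.approx(0.68, abs=3 * 0.068 / math.sqrt(20000))
        assert draws.std() == pytest.approx(0.068, rel=0.05)

    def test_lognormal_moment_matching(self):
        for mean in (16.6, 1425.1):
            spec = m.ParamDistribution("c", "lognormal", mean)
            # sigma^2 = ln(1 + s^2/m^2) is scale-free at 10% spread
            draws = m.make_distribution(spec)(np.random.default_rng(1), 50000)
            assert draws.mean() == pytest.approx(mean, rel=0.01)
            assert np.log(draws).var() == pytest.approx(math.log(1.01), rel=0.05)
            assert np.all(draws > 0)

    def test_fixed_family_is_degenerate(self):
        spec = m.ParamDistribution("discount_rate", "fixed", 0.03)
        assert np.all(m.make_distribution(spec)(np.random.default_rng(2), 10) == 0.03)

    def test_invalid_specifications_rejected(self):
        with pytest.raises(ValueError):
            m.make_distribution(m.ParamDistribution("r", "beta", 0.5, spread=0.5))
        with pytest.raises(ValueError):
            m.make_distribution(m.ParamDistribution("c", "lognormal", -3.0))
        with pytest.raises(ValueError):
            m.ParamDistribution("x", "gamma", 1.0)
        with pytest.raises(ValueError):
            m.ParamDistribution("x", "beta", 0.9, low=0.1, high=0.5)


class TestRunPSA:
    def test_seed_replay_is_bit_stable(self, bundle):
        a = m.run_psa(bundle, n=50, seed=3)
        b = m.run_psa(bundle, n=50, seed=3)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)

    def test_all_fixed_reproduces_deterministic_base_case(self, bundle, base_case):
        dists = [
            m.ParamDistribution(d.name, "fixed", d.mean, low=d.low, high=d.high)
            for d in sens.default_distributions()
        ]
        psa = m.run_psa(bundle, distributions=dists, n=5, seed=0)
        _, _, cmp_ = base_case
        np.testing.assert_allclose(psa.delta_cost, cmp_.delta_cost, rtol=1e-12)
        np.testing.assert_allclose(psa.delta_qaly, cmp_.delta_qaly, rtol=1e-12)

    def test_sampled_means_near_baselines(self, psa):
        # each sampled parameter has mean = baseline, SE = 10% of baseline
        for name, baseline in [("cost_bsc_per_cycle", 1425.1), ("utility_pd", 0.42)]:
            draws = psa.iterations[name]
            tol = 3 * 0.1 * baseline / math.sqrt(len(draws))
            assert draws.mean() == pytest.approx(baseline, abs=tol)

    def test_utility_ordering_enforced(self, psa):
        assert (psa.iterations["utility_pd"] <= psa.iterations["utility_pfs"]).all()

    def test_vanishing_spread_converges_to_base_case(self, bundle, base_case):
        dists = [
            m.ParamDistribution(d.name, d.family, d.mean, spread=1e-6 * d.mean,
                                low=d.low, high=d.high)
            for d in sens.default_distributions()
        ]
        psa = m.run_psa(bundle, distributions=dists, n=20, seed=1)
        _, _, cmp_ = base_case
        assert psa.delta_cost.mean() == pytest.approx(cmp_.delta_cost, rel=1e-4)
        assert psa.delta_qaly.mean() == pytest.approx(cmp_.delta_qaly, rel=1e-4)


class TestAcceptability:
    def test_zero_wtp_counts_cost_savings(self, psa):
        assert m.acceptability_at(psa, 1e-9) == pytest.approx(
            np.mean(psa.delta_cost < 0)
        )

    def test_large_wtp_limit_counts_qaly_gains(self, psa):
        assert m.acceptability_at(psa, 1e12) == pytest.approx(
            np.mean(psa.delta_qaly > 0)
        )
        assert m.acceptability_at(psa, 1e12) > 0.99

    def test_ceac_single_point_equals_acceptability(self, psa):
        curve = m.ceac(psa, [26022.0])
        assert curve["probability_cost_effective"].iloc[0] == m.acceptability_at(
            psa, 26022.0
        )

    def test_ceac_monotone_when_all_iterations_gain_qalys(self, psa):
        assert np.all(psa.delta_qaly > 0)
        curve = m.ceac(psa, np.linspace(0, 150000, 31))
        assert np.all(np.diff(curve["probability_cost_effective"]) >= 0)
        assert curve["probability_cost_effective"].between(0, 1).all()

    def test_near_median_acceptability_at_threshold_price(self, bundle):
        """At the price where the deterministic ICER equals the WTP, roughly
        half the Monte-Carlo draws fall on each side."""
        wtp = 56263.0
        price = m.threshold_price(bundle, wtp)
        psa = m.run_psa(bundle.with_ram_price(price), n=1000, seed=11)
        assert 0.40 <= m.acceptability_at(psa, wtp) <= 0.60

    def test_acceptability_decreases_with_price_under_common_random_numbers(
        self, bundle
    ):
        curve = m.ceac_by_price(
            bundle, price_grid=[0.0, 300.0, 900.0], wtps=[56263.0], n=150, seed=5
        )
        probs = curve["probability_cost_effective"].to_numpy()
        assert np.all(np.diff(probs) <= 0)


class TestTornado:
    def test_degenerate_range_gives_zero_width(self, bundle):
        dists = [m.ParamDistribution("utility_pd", "beta", 0.42, low=0.42, high=0.42)]
        [entry] = m.tornado(bundle, 26022.0, distributions=dists, include_ram_price=False)
        assert entry.width == 0.0

    def test_bar_endpoints_match_independent_reruns(self, bundle):
        import dataclasses

        entries = m.tornado(bundle, 26022.0)
        by_name = {e.parameter: e for e in entries}
        e = by_name["cost_bsc_per_cycle"]
        # out-of-band recomputation: rebuild the inputs by hand at each bound
        for bound, got in ((e.low_value, e.icer_at_low), (e.high_value, e.icer_at_high)):
            costs = dataclasses.replace(bundle.costs, bsc_per_cycle=bound)
            _, _, c = m.run_comparison(bundle.with_(costs=costs), 26022.0)
            assert got == pytest.approx(c.icer_per_qaly, rel=1e-12)

    def test_sorted_by_descending_swing(self, bundle):
        widths = [e.width for e in m.tornado(bundle, 26022.0)]
        assert widths == sorted(widths, reverse=True)

    def test_baseline_icer_within_bar_for_monotone_parameters(self, bundle):
        entries = m.tornado(bundle, 26022.0)
        e = {x.parameter: x for x in entries}["cost_ram_per_cycle"]
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        assert lo <= e.baseline_icer <= hi

    def test_ram_price_bar_spans_scenario_price(self, bundle):
        entries = m.tornado(bundle, 26022.0)
        e = {x.parameter: x for x in entries}["cost_ram_per_cycle"]
        assert e.low_value == pytest.approx(122.0)
        assert e.high_value == pytest.approx(366.0)


class TestApplyOverrides:
    def test_overrides_reach_every_component(self, bundle):
        new = sens.apply_overrides(
            bundle,
            {
                "cost_bsc_per_cycle": 1000.0,
                "cost_ae_neutropenia": 600.0,
                "risk_ram_neutropenia": 0.5,
                "utility_pfs": 0.7,
                "utility_pd": 0.4,
                "weight_kg": 70.0,
                "bsa_m2": 1.8,
                "discount_rate": 0.05,
            },
        )
        assert new.costs.bsc_per_cycle == 1000.0
        assert new.costs.ae_episode_costs["neutropenia"] == 600.0
        assert new.ae_profiles["ram"].risks["neutropenia"] == 0.5
        assert new.utilities.u_pfs == 0.7
        assert new.dosing.weight_kg == 70.0
        assert new.config.annual_discount_rate == 0.05
        # original untouched
        assert bundle.costs.bsc_per_cycle == 1425.1

    def test_unknown_parameter_rejected(self, bundle):
        with pytest.raises(KeyError):
            sens.apply_overrides(bundle, {"cost_of_tea": 3.0})
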