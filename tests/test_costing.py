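"""Dosing-based drug costs, adverse-event costs, and strategy costing."""

import numpy as np
import pytest

import psmcea as m
from psmcea.costing import CostingError
from conftest import params


@pytest.fixture
def dosing():
    return m.DosingSpec()  # 65 kg, 1.62 m^2


@pytest.fixture
def costs():
    from psmcea import fixtures

    return fixtures.default_costs(ram_price_per_cycle=244.0)


@pytest.fixture
def profiles():
    from psmcea import fixtures

    return {arm: fixtures.default_ae_profile(arm) for arm in ("ram", "pla")}


class TestDrugCost:
    def test_ram_at_hong_kong_per_mg_price(self, dosing):
        # 65 kg x 8 mg/kg x 2 infusions = 1040 mg/cycle at $12.2/mg
        costs = m.CostInputs(ram_price_per_mg=12.2)
        assert m.drug_cost_per_cycle(dosing, costs, "ram")["ram"] == pytest.approx(
            12688.0
        )

    def test_pac_component_from_per_30mg_price(self, dosing, costs):
        # 1.62 m^2 x 80 mg/m^2 x 3 infusions x $116.2/30 mg
        expected = 1.62 * 80 * 3 * 116.2 / 30
        for arm in ("ram", "pla"):
            assert m.drug_cost_per_cycle(dosing, costs, arm)["pac"] == pytest.approx(
                expected
            )
        assert expected == pytest.approx(1505.95, abs=0.01)

    def test_placebo_arm_has_no_ram_component(self, dosing, costs):
        assert m.drug_cost_per_cycle(dosing, costs, "pla")["ram"] == 0.0

    def test_zero_prices_give_zero(self, dosing):
        costs = m.CostInputs(pac_per_30mg=0.0, ram_price_per_cycle=0.0)
        assert m.drug_cost_per_cycle(dosing, costs, "ram") == {"ram": 0.0, "pac": 0.0}

    def test_conflicting_ram_prices_rejected(self):
        with pytest.raises(CostingError):
            m.CostInputs(ram_price_per_cycle=244.0, ram_price_per_mg=0.2343)

    def test_unknown_arm_rejected(self, dosing, costs):
        with pytest.raises(ValueError):
            m.drug_cost_per_cycle(dosing, costs, "nivolumab")


class TestPriceConversion:
    @pytest.mark.parametrize(
        "per_mg,per_cycle", [(0.2343, 243.672), (0.5808, 604.032), (12.2, 12688.0)]
    )
    def test_per_mg_per_cycle_round_trip(self, dosing, per_mg, per_cycle):
        assert m.per_mg_to_per_cycle(per_mg, dosing) == pytest.approx(per_cycle)
        assert m.per_cycle_to_per_mg(per_cycle, dosing) == pytest.approx(per_mg)


class TestAdverseEventCost:
    def test_published_risk_cost_products(self, costs, profiles):
        # sum of risk_i x episode cost_i over the five grade-3/4 categories
        ram = 0.15 * 116.2 + 0.098 * 44.6 + 0.043 * 40.0 + 0.41 * 534.4 + 0.14 * 16.6
        pla = 0.094 * 116.2 + 0.043 * 44.6 + 0.061 * 40.0 + 0.19 * 534.4 + 0.02 * 16.6
        assert m.expected_ae_cost(profiles["ram"], costs) == pytest.approx(ram)
        assert m.expected_ae_cost(profiles["pla"], costs) == pytest.approx(pla)
        assert ram == pytest.approx(244.95, abs=0.01)
        assert pla == pytest.approx(117.15, abs=0.01)

    def test_zero_risks_give_zero(self, costs):
        profile = m.AEProfile(risks={k: 0.0 for k in costs.ae_episode_costs})
        assert m.expected_ae_cost(profile, costs) == 0.0

    def test_mismatched_categories_rejected(self, costs):
        profile = m.AEProfile(risks={"neutropenia": 0.1})
        with pytest.raises(CostingError):
            m.expected_ae_cost(profile, costs)

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(ValueError):
            m.AEProfile(risks={"neutropenia": 1.2})


class TestStrategyCost:
    @pytest.fixture
    def trace(self, cfg):
        return m.build_trace(params("ram", "pfs"), params("ram", "os"), cfg)

    def test_matches_independent_per_cycle_recomputation(
        self, trace, dosing, costs, profiles, cfg
    ):
        """Brute-force oracle: loop cycles, accrue each item separately."""
        per_cycle_pfs = (
            244.0  # ram
            + 1.62 * 80 * 3 * 116.2 / 30  # pac
            + 3 * 18.6  # administration, 3 infusion days
            + 88.2  # laboratory
            + 105.9 * 28 / 42  # CT every 6 weeks
        )
        total = 0.15 * 116.2 + 0.098 * 44.6 + 0.043 * 40 + 0.41 * 534.4 + 0.14 * 16.6
        for u in range(cfg.n_cycles):
            pfs_mid = 0.5 * (
                trace.pfs[u] * trace.discount[u]
                + trace.pfs[u + 1] * trace.discount[u + 1]
            )
            pd_mid = 0.5 * (
                trace.pd[u] * trace.discount[u]
                + trace.pd[u + 1] * trace.discount[u + 1]
            )
            total += per_cycle_pfs * pfs_mid + 1425.1 * pd_mid
        breakdown = m.strategy_cost(trace, dosing, costs, profiles["ram"], cfg, "ram")
        assert breakdown.total == pytest.approx(total, rel=1e-9)

    def test_itemised_components_sum_to_total(self, trace, dosing, costs, profiles, cfg):
        breakdown = m.strategy_cost(trace, dosing, costs, profiles["ram"], cfg, "ram")
        assert breakdown.total == pytest.approx(
            sum(v for _, v in breakdown.items.values()), rel=1e-12
        )
        assert set(breakdown.items) == {
            "drug_ram",
            "drug_pac",
            "administration",
            "laboratory",
            "imaging_ct",
            "best_supportive_care",
            "adverse_events",
        }

    def test_empty_horizon_leaves_only_ae_cost(self, dosing, costs, profiles):
        cfg0 = m.ModelConfig(horizon_years=0.05)
        trace = m.build_trace(params("ram", "pfs"), params("ram", "os"), cfg0)
        breakdown = m.strategy_cost(trace, dosing, costs, profiles["ram"], cfg0, "ram")
        assert breakdown.total == pytest.approx(
            m.expected_ae_cost(profiles["ram"], costs)
        )

    def test_linearity_in_unit_prices(self, trace, dosing, costs, profiles, cfg):
        import dataclasses

        doubled = dataclasses.replace(
            costs,
            pac_per_30mg=2 * costs.pac_per_30mg,
            admin_per_unit=2 * costs.admin_per_unit,
            lab_per_unit=2 * costs.lab_per_unit,
            bsc_per_cycle=2 * costs.bsc_per_cycle,
            ct_per_unit=2 * costs.ct_per_unit,
            ae_episode_costs={k: 2 * v for k, v in costs.ae_episode_costs.items()},
            ram_price_per_cycle=2 * costs.ram_price_per_cycle,
        )
        one = m.strategy_cost(trace, dosing, costs, profiles["ram"], cfg, "ram")
        two = m.strategy_cost(trace, dosing, doubled, profiles["ram"], cfg, "ram")
        assert two.total == pytest.approx(2 * one.total, rel=1e-12)

    def test_placebo_cost_ignores_ram_price(self, trace, dosing, profiles, cfg):
        from psmcea import fixtures

        a = m.strategy_cost(
            trace, dosing, fixtures.default_costs(244.0), profiles["pla"], cfg, "pla"
        )
        b = m.strategy_cost(
            trace, dosing, fixtures.default_costs(9999.0), profiles["pla"], cfg, "pla"
        )
        assert a.total == b.total

    def test_more_pd_occupancy_costs_more_bsc(self, dosing, costs, profiles, cfg):
        n = cfg.n_cycles + 1
        base = dict(
            t_months=cfg.months_at(np.arange(n)),
            pfs=np.full(n, 0.3),
            discount=cfg.discount_factor(np.arange(n)),
        )
        small = m.CohortTrace(pd=np.full(n, 0.2), dead=np.full(n, 0.5), **base)
        large = m.CohortTrace(pd=np.full(n, 0.5), dead=np.full(n, 0.2), **base)
        cost_small = m.strategy_cost(small, dosing, costs, profiles["ram"], cfg, "ram")
        cost_large = m.strategy_cost(large, dosing, costs, profiles["ram"], cfg, "ram")
        assert (
            cost_large.items["best_supportive_care"][1]
            > cost_small.items["best_supportive_care"][1]
        )
        assert cost_large.items["drug_ram"] == cost_small.items["drug_ram"]


class TestRegimenCost:
    def test_published_worked_example(self):
        # (65 x 2 x 8 x 12.2 + 1.67 x 80 x 3 x 154.6/30) x 13
        dosing = m.DosingSpec(weight_kg=65.0, bsa_m2=1.67)
        cost = m.regimen_annual_cost(dosing, c1_per_mg=12.2, c2_per_30mg=154.6)
        assert cost == pytest.approx(191794.93, abs=0.01)

    def test_zero_cycles_or_prices_give_zero(self):
        dosing = m.DosingSpec()
        assert m.regimen_annual_cost(dosing, 12.2, 154.6, n_cycles=0) == 0.0
        assert m.regimen_annual_cost(dosing, 0.0, 0.0) == 0.0
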