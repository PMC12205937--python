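import numpy as np
import pytest

from coyield import (CocultureSpec, Exchange, mapping_constant,
                     mapping_multiplier, simulate_production, strain_state)
from coyield.fixtures import ToySpec, toy_model, toy_pair


class TestMappingMultiplier:
    def test_constant_substrate_gives_unity(self):
        assert mapping_multiplier(10.0, [0, 1, 2], [10, 10, 10]) == pytest.approx(1.0)

    def test_linear_decay_gives_two(self):
        assert mapping_multiplier(10.0, [0, 3, 6], [10, 5, 0]) == pytest.approx(2.0)

    def test_trapezoid_hand_value(self):
        # average = ((10+4)/2 + (4+1)/2)/2 = 4.75
        k = mapping_multiplier(10.0, [0, 1, 2], [10, 4, 1])
        assert k == pytest.approx(10.0 / 4.75)

    def test_fully_depleted_record_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            mapping_multiplier(10.0, [0, 1], [0.0, 0.0])


class TestMappingConstant:
    @pytest.mark.parametrize("k_per,icr,expected", [
        ((2.0, 4.0), (0.5, 0.5), 3.0),
        ((2.0, 4.0), (1.0, 0.0), 2.0),
        ((10.0 / 4.75, 1.5), (0.8, 0.2), 0.8 * 10.0 / 4.75 + 0.3),
    ])
    def test_weighted_combination(self, k_per, icr, expected):
        assert mapping_constant(k_per, icr).k == pytest.approx(expected)

    def test_unnormalized_fractions_rejected_unless_flagged(self):
        with pytest.raises(ValueError, match="normalize"):
            mapping_constant((2.0, 4.0), (1.0, 4.0))
        mc = mapping_constant((2.0, 4.0), (1.0, 4.0), normalize=True)
        assert mc.icr == pytest.approx((0.2, 0.8))


def two_independent_strains(d=0.1):
    """Two strains with no cross-feeding; both products count."""
    a = strain_state(toy_model(ToySpec(), strain_id="a"), d)
    b = strain_state(toy_model(ToySpec(), strain_id="b"), d)
    return a, b


class TestIntegrator:
    def test_single_strain_closed_form(self):
        # v_prod = 1 (d = 0.1 on a 10-unit chain), k = 2, 60 steps of 0.1 h
        a, b = two_independent_strains(d=0.1)
        spec = CocultureSpec(strains=(a, b), icr=(1.0, 0.0), dt=0.1, tp=60)
        pred = simulate_production(spec, 2.0)
        assert pred.total == pytest.approx(2.0 * 1.0 * 1.0 * 0.1 * 60)

    def test_total_linear_in_k_and_tp_when_nothing_binds(self):
        a, b = two_independent_strains()
        base = simulate_production(
            CocultureSpec(strains=(a, b), icr=(0.5, 0.5), dt=0.1, tp=30), 1.0)
        double_k = simulate_production(
            CocultureSpec(strains=(a, b), icr=(0.5, 0.5), dt=0.1, tp=30), 2.0)
        double_tp = simulate_production(
            CocultureSpec(strains=(a, b), icr=(0.5, 0.5), dt=0.1, tp=60), 1.0)
        assert double_k.total == pytest.approx(2 * base.total)
        assert double_tp.total == pytest.approx(2 * base.total)

    def test_degenerate_consortium_reduces_to_scaled_monoculture(self):
        a, b = two_independent_strains(d=0.25)
        spec = CocultureSpec(strains=(a, b), icr=(1.0, 0.0), dt=0.1, tp=60)
        k = mapping_constant((2.105, 1.5), (1.0, 0.0))
        pred = simulate_production(spec, k)
        expected = k.k * a.production_flux * 0.1 * 60
        assert pred.total == pytest.approx(expected)

    def test_demand_exceeding_supply_tracks_the_pool(self):
        # upstream secretes d_up·10 = 2/h; downstream demands its full
        # 4-unit uptake: with equal fractions demand is twice supply
        up_m, down_m, exchanges = toy_pair(ToySpec(), ToySpec(uptake_bound=4.0))
        up = strain_state(up_m, 0.2, substrate_met="glc")
        down = strain_state(down_m, 0.5, substrate_met="emet")
        spec = CocultureSpec(strains=(up, down), icr=(0.5, 0.5), dt=0.1, tp=60,
                             exchange_map=exchanges)
        pred = simulate_production(spec, 1.0)
        secreted = 1.0 * 2.0 * 0.5 * 0.1 * 60  # k·v_sec·icr_up·dt·tp
        yield_down = down.production_flux / 4.0  # product per emet taken up
        assert pred.total == pytest.approx(secreted * yield_down)
        assert pred.exchange_pools["emet"][-1] == pytest.approx(0.0, abs=1e-12)

    def test_pools_never_negative_with_capping(self, consortium):
        up_m, down_m, exchanges = consortium
        up = strain_state(up_m, 0.035)
        down = strain_state(down_m, 0.011)
        for icr in [(0.8, 0.2), (0.5, 0.5), (0.2, 0.8)]:
            spec = CocultureSpec(strains=(up, down), icr=icr, dt=0.1, tp=60,
                                 exchange_map=exchanges)
            pred = simulate_production(spec, 1.5)
            assert all(p >= -1e-12 for p in pred.exchange_pools["emet"])

    def test_capping_disabled_reports_first_violation(self, consortium):
        up_m, down_m, exchanges = consortium
        up = strain_state(up_m, 0.01)
        down = strain_state(down_m, 0.5)
        spec = CocultureSpec(strains=(up, down), icr=(0.2, 0.8), dt=0.1, tp=10,
                             exchange_map=exchanges)
        pred = simulate_production(spec, 1.0, cap_uptake=False)
        assert any("negative" in w for w in pred.warnings)
        assert min(pred.exchange_pools["emet"]) < 0

    def test_substrate_supply_cap_stops_integration_early(self):
        a, b = two_independent_strains(d=0.5)
        a.substrate_met = "glc"
        b.substrate_met = "glc"
        spec = CocultureSpec(strains=(a, b), icr=(0.5, 0.5), dt=0.1, tp=60,
                             substrate_supply=10.0)
        pred = simulate_production(spec, 1.0)
        # substrate drains at k·10·dt = 1 per step: cap reached at step 10
        assert pred.steps_run == 10
        assert pred.substrate_consumed == pytest.approx(10.0)
        assert any("exhausted" in w for w in pred.warnings)

    def test_mass_conservation_against_composite_yield(self, consortium):
        # unit stoichiometry end to end: product ≤ glucose consumed
        up_m, down_m, exchanges = consortium
        up = strain_state(up_m, 0.05, substrate_met="glc")
        down = strain_state(down_m, 0.02, substrate_met="emet")
        down.substrate_met = None  # count external glucose only
        for icr in [(0.9, 0.1), (0.5, 0.5), (0.1, 0.9)]:
            spec = CocultureSpec(strains=(up, down), icr=icr, dt=0.1, tp=60,
                                 exchange_map=exchanges)
            pred = simulate_production(spec, 2.0)
            assert pred.total <= pred.substrate_consumed + 1e-9

    def test_horizon_mismatch_warns(self):
        a, b = two_independent_strains()
        spec = CocultureSpec(strains=(a, b), icr=(0.5, 0.5), dt=0.1, tp=60,
                             horizon=5.0)
        pred = simulate_production(spec, 1.0)
        assert any("horizon" in w for w in pred.warnings)

    def test_unnormalized_inoculum_rejected(self):
        a, b = two_independent_strains()
        with pytest.raises(ValueError, match="sum to 1"):
            CocultureSpec(strains=(a, b), icr=(0.5, 0.6), dt=0.1, tp=60)
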