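import math

import pytest

from coyield import (SolveOptions, ThermoConfig, build_driving_forces,
                     fba_max_growth, max_production, solve_mdf)
from coyield.fixtures import ToySpec, toy_model
from coyield.model import ModelConfigError

from oracles import grid_mdf

THERMO = SolveOptions(use_thermo=True)


class TestDrivingForces:
    def test_equal_concentrations_cancel(self, chain1, config):
        exprs = build_driving_forces(chain1, config)
        a, coefs = exprs["C1"]
        ln = math.log(1e-4)
        assert a + sum(b * ln for b in coefs.values()) == pytest.approx(10.0)

    def test_hand_value_at_extreme_concentrations(self, chain1, config):
        # substrate at 1e-2 M, product at 1e-6 M: Df = 10 + RT·ln(1e4)
        a, coefs = build_driving_forces(chain1, config)["C1"]
        df = a + coefs["glc"] * math.log(1e-2) + coefs["node"] * math.log(1e-6)
        assert df == pytest.approx(10.0 + config.RT * math.log(1e4))

    def test_forward_reverse_expressions_are_negatives(self, pair_model, config):
        exprs = build_driving_forces(pair_model, config)
        af, cf = exprs["Rpair"]
        ar, cr = exprs["Rpair_reverse"]
        ln = {"node": math.log(3e-4), "w": math.log(8e-6)}
        df_f = af + sum(b * ln[m] for m, b in cf.items())
        df_r = ar + sum(b * ln[m] for m, b in cr.items())
        assert df_f == pytest.approx(-df_r)

    def test_missing_annotation_is_config_error(self, config):
        m = toy_model(ToySpec(dG0_list=(-10.0, -10.0)))
        m.reaction("C1").dG0_prime = None
        with pytest.raises(ModelConfigError, match="dG0_prime"):
            build_driving_forces(m, config)

    def test_untracked_metabolites_excluded(self, config):
        m = toy_model(ToySpec(n_chain=1, dG0_list=(-10.0,)))
        m.metabolite("glc").thermo_tracked = False
        _, coefs = build_driving_forces(m, config)["C1"]
        assert "glc" not in coefs


class TestGrowth:
    def test_uptake_bound_is_the_bottleneck(self, chain2):
        sol = fba_max_growth(chain2)
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0)

    def test_enzyme_pool_caps_growth(self):
        # Σ v·mw/kcat = 2v/10 ≤ 1.2  ⇒  v ≤ 6 < uptake bound 10
        m = toy_model(ToySpec(kcat_list=(10.0, 10.0), enzyme_pool=1.2))
        sol = fba_max_growth(m, SolveOptions(use_kinetic=True))
        assert sol.objective_value == pytest.approx(6.0)

    def test_nonbinding_pool_leaves_optimum_unchanged(self):
        m = toy_model(ToySpec(kcat_list=(10.0, 10.0)))
        free = fba_max_growth(m).objective_value
        # pool exactly equal to the usage at the unconstrained optimum
        usage = sum(free * 1.0 / 10.0 for _ in range(2))
        m.enzyme_pool = usage
        sol = fba_max_growth(m, SolveOptions(use_kinetic=True))
        assert sol.objective_value == pytest.approx(free)

    def test_forced_flux_through_thermo_blocked_reaction_infeasible(self, config):
        # ΔrG'° = +100 keeps Df below 0 anywhere in the box, yet flux_lb > 0
        m = toy_model(ToySpec(n_chain=1, dG0_list=(100.0,)))
        m.reaction("C1").flux_lb = 0.1
        sol = fba_max_growth(m, THERMO, config)
        assert sol.status == "infeasible"

    def test_thermo_constraints_never_raise_the_optimum(self, config):
        m = toy_model(ToySpec(dG0_list=(-10.0, 30.0)))
        plain = fba_max_growth(m).objective_value
        constrained = fba_max_growth(m, THERMO, config)
        assert constrained.objective_value <= plain + 1e-6


class TestProduction:
    def test_growth_floor_splits_carbon(self, chain2):
        sol = max_production(chain2, growth_lb=7.5)
        assert sol.fluxes["R_prod"] == pytest.approx(2.5)
        assert sol.fluxes["R_bio"] >= 7.5 - 1e-9

    def test_full_growth_floor_leaves_no_carbon(self, chain2):
        vmax = fba_max_growth(chain2).objective_value
        sol = max_production(chain2, growth_lb=vmax)
        assert sol.fluxes["R_prod"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_floor_gives_uptake_limited_production(self, chain2):
        sol = max_production(chain2, growth_lb=0.0)
        assert sol.fluxes["R_prod"] == pytest.approx(10.0)

    def test_floor_above_max_growth_is_infeasible(self, chain2):
        sol = max_production(chain2, growth_lb=11.0)
        assert sol.status == "infeasible"

    def test_raising_floor_never_raises_production(self, chain2):
        prods = [max_production(chain2, g).fluxes["R_prod"]
                 for g in (0.0, 2.5, 5.0, 7.5, 10.0)]
        assert all(a >= b - 1e-9 for a, b in zip(prods, prods[1:]))


class TestMdf:
    def test_single_reaction_matches_grid_oracle(self, chain1, config):
        sol = solve_mdf(chain1, {"C1"}, THERMO, config)
        b_grid, res = grid_mdf(chain1, ["C1"], config)
        assert sol.B == pytest.approx(b_grid, abs=res)
        # closed form: 10 + RT·ln(Cmax/Cmin)
        assert sol.B == pytest.approx(10.0 + config.RT * math.log(1e4), abs=1e-6)

    def test_two_step_chain_equalizes_driving_forces(self, chain2, config):
        sol = solve_mdf(chain2, {"C1", "C2"}, THERMO, config)
        assert sol.B == pytest.approx(10.0 + config.RT * math.log(1e4) / 2,
                                      abs=1e-6)
        assert sol.driving_forces["C1"] == pytest.approx(sol.driving_forces["C2"],
                                                         abs=1e-6)

    def test_reversible_pair_forced_active_pins_B_at_zero(self, pair_model):
        sol = solve_mdf(pair_model, {"C1", "C2", "Rpair", "Rpair_reverse"}, THERMO)
        assert sol.B == pytest.approx(0.0, abs=1e-9)

    def test_widening_concentration_interval_never_decreases_B(self, config):
        m = toy_model(ToySpec(dG0_list=(-3.0, -4.0)))
        base = solve_mdf(m, {"C1", "C2"}, THERMO, config).B
        wide = m.copy()
        wide.metabolite("glc").ln_conc_ub += 1.0
        assert solve_mdf(wide, {"C1", "C2"}, THERMO, config).B >= base - 1e-9

    def test_big_K_insensitivity(self, chain2):
        sols = [
            solve_mdf(chain2, {"C1", "C2"}, THERMO, ThermoConfig(big_K=K))
            for K in (1000.0, 10000.0)
        ]
        assert sols[0].B == pytest.approx(sols[1].B, abs=1e-6)
        for rid in ("C1", "C2"):
            assert sols[0].fluxes[rid] == pytest.approx(sols[1].fluxes[rid],
                                                        abs=1e-6)

    def test_free_binaries_may_switch_off_unfavorable_reaction(self, config):
        # second step thermodynamically impossible: the MILP deactivates it
        m = toy_model(ToySpec(dG0_list=(-10.0, 100.0)))
        sol = solve_mdf(m, {"C1"}, THERMO, config)
        assert sol.ok
        assert sol.z["C2"] == 0
        assert sol.fluxes["C2"] == pytest.approx(0.0, abs=1e-6)

    def test_requires_thermo_annotations(self, config):
        m = toy_model(ToySpec())
        with pytest.raises(ModelConfigError):
            solve_mdf(m, {"C1"}, THERMO, config)
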