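import dataclasses
import math

import pandas as pd
import pytest

from coyield import (MetabolicModel, Metabolite, ModelConfigError,
                     ModelFormatError, Reaction, attach_kinetics,
                     attach_thermo, load_model, save_model)
from coyield.fixtures import ToySpec, toy_model


def thermo_table(rows):
    return pd.DataFrame(rows, columns=["reaction_id", "dG0_prime_kJ_mol"])


class TestRepresentation:
    def test_toy_chain_has_expected_shape(self):
        m = toy_model(ToySpec(dG0_list=(-10.0, -10.0)))
        assert len(m.reactions) == 6
        assert m.biomass_reaction().id == "R_bio"
        assert m.production_reaction().id == "R_prod"

    def test_invalid_concentration_window_rejected(self):
        with pytest.raises(ValueError, match="ln_conc_lb"):
            Metabolite(id="a", ln_conc_lb=0.0, ln_conc_ub=-1.0)

    def test_undefined_stoichiometry_reference_rejected(self):
        with pytest.raises(ValueError, match="undefined metabolites"):
            MetabolicModel(
                metabolites=[Metabolite(id="a")],
                reactions=[Reaction(id="r", stoich={"a": -1.0, "ghost": 1.0})])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MetabolicModel(
                metabolites=[Metabolite(id="a"), Metabolite(id="a")],
                reactions=[Reaction(id="r", stoich={"a": -1.0})])

    def test_two_biomass_reactions_rejected(self):
        with pytest.raises(ValueError, match="biomass"):
            MetabolicModel(
                metabolites=[Metabolite(id="a")],
                reactions=[
                    Reaction(id="r1", stoich={"a": -1.0}, role="biomass"),
                    Reaction(id="r2", stoich={"a": -1.0}, role="biomass"),
                ])


class TestJsonRoundTrip:
    def test_round_trip_is_identity_field_by_field(self, tmp_path):
        spec = ToySpec(dG0_list=(-10.0, -5.0), kcat_list=(100.0, 200.0),
                       enzyme_pool=0.227, include_reverse_pair=True)
        m = toy_model(spec)
        path = tmp_path / "toy.json"
        save_model(m, path)
        m2 = load_model(path)
        assert m2.strain_id == m.strain_id
        assert m2.enzyme_pool == m.enzyme_pool
        for a, b in zip(m.metabolites, m2.metabolites):
            assert dataclasses.asdict(a) == dataclasses.asdict(b)
        for a, b in zip(m.reactions, m2.reactions):
            assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"metabolites": [')
        with pytest.raises(ModelFormatError, match="JSON"):
            load_model(path)

    def test_missing_reactions_array_rejected(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text('{"metabolites": []}')
        with pytest.raises(ModelFormatError, match="reactions"):
            load_model(path)

    def test_no_biomass_is_configuration_error(self, tmp_path):
        import json

        doc = {"metabolites": [{"id": "a"}],
               "reactions": [{"id": "r1", "metabolites": {"a": -1.0},
                              "lower_bound": 0, "upper_bound": 10}]}
        path = tmp_path / "nobio.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelConfigError, match="biomass"):
            load_model(path)

    def test_biomass_found_by_id_pattern_without_objective(self, tmp_path):
        m = toy_model(ToySpec())
        m.reaction("R_bio").role = "internal"  # drop designation+objective
        path = tmp_path / "pattern.json"
        save_model(m, path)
        assert load_model(path).biomass_reaction().id == "R_bio"

    def test_water_and_protons_not_tracked(self, tmp_path):
        m = MetabolicModel(
            metabolites=[Metabolite(id="glc_c"), Metabolite(id="h2o_c"),
                         Metabolite(id="h_c")],
            reactions=[Reaction(id="bio", stoich={"glc_c": -1.0, "h2o_c": 1.0,
                                                  "h_c": 1.0}, role="biomass")])
        path = tmp_path / "wm.json"
        save_model(m, path)
        m2 = load_model(path)
        assert m2.metabolite("glc_c").thermo_tracked
        assert not m2.metabolite("h2o_c").thermo_tracked
        assert not m2.metabolite("h_c").thermo_tracked


class TestSbml:
    def test_sbml_load_detects_objective_biomass(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("mini")
        a = cobra.Metabolite("a_c", compartment="c")
        growth = cobra.Reaction("Growth")
        growth.add_metabolites({a: -1.0})
        uptake = cobra.Reaction("EX_a")
        uptake.add_metabolites({a: 1.0})
        uptake.bounds = (0, 5)
        cm.add_reactions([growth, uptake])
        cm.objective = "Growth"
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cm, str(path))
        m = load_model(path)
        assert m.biomass_reaction().id == "Growth"
        assert m.reaction("EX_a").flux_ub == 5

    def test_truncated_sbml_is_format_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><model><listOfSpecies>")
        with pytest.raises(ModelFormatError):
            load_model(path, format="sbml")


class TestAttachThermo:
    def test_values_set_and_marked_in_pathway(self):
        m = toy_model(ToySpec())
        m2 = attach_thermo(m, thermo_table([("C1", -10.0)]))
        assert m2.reaction("C1").dG0_prime == -10.0
        assert m2.reaction("C1").in_pathway
        assert m.reaction("C1").dG0_prime is None  # original untouched

    def test_reverse_pair_antisymmetry_accepted(self):
        m = toy_model(ToySpec(include_reverse_pair=True))
        m2 = attach_thermo(m, thermo_table(
            [("Rpair", 7.5), ("Rpair_reverse", -7.5)]))
        assert m2.reaction("Rpair_reverse").dG0_prime == -7.5

    def test_reverse_pair_non_negated_rejected(self):
        m = toy_model(ToySpec(include_reverse_pair=True))
        with pytest.raises(ValueError, match="not negated"):
            attach_thermo(m, thermo_table(
                [("Rpair", 7.5), ("Rpair_reverse", 7.5)]))

    def test_unknown_reaction_rejected(self):
        m = toy_model(ToySpec())
        with pytest.raises(KeyError, match="unknown reaction"):
            attach_thermo(m, thermo_table([("nope", 1.0)]))

    def test_tsv_file_round_trip(self, tmp_path):
        m = toy_model(ToySpec())
        path = tmp_path / "thermo.tsv"
        thermo_table([("C1", -10.0), ("C2", 2.5)]).to_csv(
            path, sep="\t", index=False)
        m2 = attach_thermo(m, path)
        assert m2.reaction("C2").dG0_prime == 2.5


class TestAttachKinetics:
    @pytest.mark.parametrize("kcat", [6503.76, 557.18])
    def test_values_set(self, kcat):
        m = toy_model(ToySpec())
        table = pd.DataFrame(
            [("R_prod", kcat, 1.0)],
            columns=["reaction_id", "kcat_per_h_per_g", "mw_g_per_mmol"])
        m2 = attach_kinetics(m, table)
        assert m2.reaction("R_prod").kcat == kcat
        assert m2.reaction("R_prod").mw == 1.0
        assert math.isclose(m2.enzyme_pool, 0.227)

    def test_nonpositive_kcat_rejected(self):
        m = toy_model(ToySpec())
        table = pd.DataFrame(
            [("R_prod", 0.0, 1.0)],
            columns=["reaction_id", "kcat_per_h_per_g", "mw_g_per_mmol"])
        with pytest.raises(ValueError, match="positive"):
            attach_kinetics(m, table)
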