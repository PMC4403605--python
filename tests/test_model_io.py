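"""Equation parsing, tabular and SBML round trips, scenario files."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyanoflux import MetabolicModel, Metabolite, Reaction, build_stoich_matrix
from cyanoflux.exceptions import ScenarioError, StructuralError
from cyanoflux.io import (format_equation, parse_equation, read_sbml_model,
                          read_scenario_config, read_tabular_model,
                          write_sbml_model, write_tabular_model)


class TestEquationParser:
    @pytest.mark.parametrize("text,stoich,reversible", [
        ("Pyruvate => Acetaldehyde + CO2",
         {"Pyruvate": -1, "Acetaldehyde": 1, "CO2": 1}, False),
        ("2 A <=> B", {"A": -2, "B": 1}, True),
        ("14/3 h_l + adp => atp", {"h_l": Fraction(-14, 3), "adp": -1, "atp": 1},
         False),
        ("0.5 o2 + pqh2 => pq + h2o",
         {"o2": Fraction(-1, 2), "pqh2": -1, "pq": 1, "h2o": 1}, False),
        ("photon_e =>", {"photon_e": -1}, False),
    ])
    def test_examples(self, text, stoich, reversible):
        got, rev = parse_equation(text)
        assert got == {k: Fraction(v) for k, v in stoich.items()}
        assert rev is reversible

    @pytest.mark.parametrize("bad", ["A - B", "A => 1.2.3 B", "=>"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_equation(bad)

    @settings(max_examples=60, derandomize=True)
    @given(st.dictionaries(
        st.sampled_from([f"m{i}" for i in range(8)]),
        st.fractions(min_value=Fraction(-20), max_value=Fraction(20),
                     max_denominator=7).filter(lambda f: f != 0),
        min_size=1, max_size=5),
        st.booleans())
    def test_format_parse_round_trip(self, stoich, reversible):
        rxn = Reaction("R", stoichiometry=stoich,
                       lower_bound=-10.0 if reversible else 0.0, upper_bound=10.0)
        parsed, rev = parse_equation(format_equation(rxn))
        assert parsed == rxn.stoichiometry
        assert rev is reversible


class TestTabularDialect:
    def test_round_trip_preserves_stoichiometry(self, core_full, tmp_path):
        rxn_path, met_path = tmp_path / "r.tsv", tmp_path / "m.tsv"
        write_tabular_model(core_full, rxn_path, met_path)
        again = read_tabular_model(rxn_path, met_path)
        assert again.reaction_ids == core_full.reaction_ids
        assert np.allclose(build_stoich_matrix(again).toarray(),
                           build_stoich_matrix(core_full).toarray())
        assert again.objective == core_full.objective
        assert again.reaction("PSII").pseudo
        assert again.metabolite("atp_c").formula == \
               core_full.metabolite("atp_c").formula

    def test_empty_tables_give_empty_model(self, tmp_path):
        (tmp_path / "r.tsv").write_text("id\tname\tequation\n")
        (tmp_path / "m.tsv").write_text("id\tname\n")
        model = read_tabular_model(tmp_path / "r.tsv", tmp_path / "m.tsv")
        assert model.reactions == [] and model.metabolites == []

    def test_default_bounds_by_arrow(self, tmp_path):
        (tmp_path / "m.tsv").write_text("id\nA\nB\n")
        (tmp_path / "r.tsv").write_text(
            "id\tequation\tlower_bound\tupper_bound\n"
            "Rf\tA => B\t\t\n"
            "Rr\t2 A <=> B\t\t\n")
        model = read_tabular_model(tmp_path / "r.tsv", tmp_path / "m.tsv")
        assert (model.reaction("Rf").lower_bound,
                model.reaction("Rf").upper_bound) == (0.0, 1000.0)
        assert (model.reaction("Rr").lower_bound,
                model.reaction("Rr").upper_bound) == (-1000.0, 1000.0)
        assert model.reaction("Rr").stoichiometry == {"A": -2, "B": 1}

    def test_unknown_metabolite_names_row(self, tmp_path):
        (tmp_path / "m.tsv").write_text("id\nA\n")
        (tmp_path / "r.tsv").write_text("id\tequation\nR9\tA => Z\n")
        with pytest.raises(StructuralError, match="R9"):
            read_tabular_model(tmp_path / "r.tsv", tmp_path / "m.tsv")


class TestSbml:
    def test_minimal_one_reaction_round_trip(self, tmp_path):
        m = MetabolicModel("mini")
        m.add_metabolite(Metabolite("a_c", formula={"C": 1, "H": 4}))
        m.add_metabolite(Metabolite("b_c", formula={"C": 1, "H": 4}))
        m.add_reaction(Reaction("R1", stoichiometry={"a_c": -1, "b_c": 1},
                                lower_bound=0, upper_bound=10))
        path = tmp_path / "mini.xml"
        write_sbml_model(m, path)
        again = read_sbml_model(path)
        assert len(again.reactions) == 1
        assert again.reaction("R1").stoichiometry == {"a_c": -1, "b_c": 1}

    def test_core_round_trip_is_stoichiometric_fixed_point(self, core_full, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml_model(core_full, p1)
        once = read_sbml_model(p1)
        write_sbml_model(once, p2)
        twice = read_sbml_model(p2)
        S1 = build_stoich_matrix(once).toarray()
        S2 = build_stoich_matrix(twice).toarray()
        assert once.reaction_ids == twice.reaction_ids
        assert np.allclose(S1, S2)
        assert all(r1.lower_bound == r2.lower_bound
                   and r1.upper_bound == r2.upper_bound
                   for r1, r2 in zip(once.reactions, twice.reactions))
        assert once.objective == twice.objective

    def test_sbml_and_tabular_agree(self, core_base, tmp_path):
        write_sbml_model(core_base, tmp_path / "m.xml")
        write_tabular_model(core_base, tmp_path / "r.tsv", tmp_path / "m.tsv")
        from_sbml = read_sbml_model(tmp_path / "m.xml")
        from_tab = read_tabular_model(tmp_path / "r.tsv", tmp_path / "m.tsv")
        met_order = {m.id: i for i, m in enumerate(from_sbml.metabolites)}
        rxn_order = {r.id: j for j, r in enumerate(from_sbml.reactions)}
        S_sbml = build_stoich_matrix(from_sbml).toarray()
        S_tab = build_stoich_matrix(from_tab).toarray()
        rows = [met_order[m.id] for m in from_tab.metabolites]
        cols = [rxn_order[r.id] for r in from_tab.reactions]
        assert np.allclose(S_tab, S_sbml[np.ix_(rows, cols)])

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model>truncated")
        with pytest.raises(StructuralError):
            read_sbml_model(bad)


class TestScenarioFiles:
    def test_transition_values_recognized(self, tmp_path):
        p = tmp_path / "s.cfg"
        p.write_text("# wild-type preset\nmaintenance_atp 0.6312\n"
                     "photon_influx 18.0\n")
        scen = read_scenario_config(p)
        assert scen.name == "transition_mode"
        assert scen.maintenance_atp == 0.6312
        assert scen.photon_influx == 18.0
        assert scen.oxygenase_fraction == 0.03

    def test_empty_file_gives_yield_defaults(self, tmp_path):
        p = tmp_path / "empty.cfg"
        p.write_text("# nothing\n")
        scen = read_scenario_config(p)
        assert scen.name == "yield_mode"
        assert scen.maintenance_atp == 0.0
        assert scen.photon_influx == pytest.approx(15.57)

    def test_oxygenase_fraction_stored_as_three_percent(self, tmp_path):
        p = tmp_path / "ox.cfg"
        p.write_text("oxygenase_fraction 0.03\n")
        assert read_scenario_config(p).oxygenase_fraction == 0.03

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "u.cfg"
        p.write_text("warp_drive 9\n")
        with pytest.raises(ScenarioError, match="warp_drive"):
            read_scenario_config(p)

    def test_negative_light_rejected(self, tmp_path):
        p = tmp_path / "n.cfg"
        p.write_text("photon_influx -3\n")
        with pytest.raises(ScenarioError):
            read_scenario_config(p)
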