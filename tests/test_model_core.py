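import pytest

from cofactorflux.model_core import (
    And,
    Gene,
    MetabolicModel,
    Or,
    Reaction,
    SBO_PSEUDO_METABOLITE,
    Species,
    SpeciesCategory,
    diff_models,
    find_dead_ends,
    parse_gpr,
    read_sbml,
    write_sbml,
)


class TestGPR:
    def test_parse_single_gene(self):
        gpr = parse_gpr("g1")
        assert isinstance(gpr, Gene)
        assert gpr.genes() == {"g1"}

    def test_and_binds_tighter_than_or(self):
        gpr = parse_gpr("g1 or g2 and g3")
        assert isinstance(gpr, Or)
        assert gpr.to_string() == "g1 or (g2 and g3)"
        # g2 knocked out: g1 alone still carries
        assert gpr.evaluate({"g2"})
        # g1 and g3 knocked out: nothing carries
        assert not gpr.evaluate({"g1", "g3"})

    def test_parentheses(self):
        gpr = parse_gpr("(g1 or g2) and g3")
        assert isinstance(gpr, And)
        assert not gpr.evaluate({"g3"})
        assert gpr.evaluate({"g1"})

    def test_round_trip(self):
        for text in ("g1", "g1 and g2", "g1 or g2 and g3", "(g1 or g2) and g3"):
            gpr = parse_gpr(text)
            assert parse_gpr(gpr.to_string()) == gpr

    def test_empty_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr(None) is None

    @pytest.mark.parametrize("bad", ["g1 and", "(g1", "g1 g2", "and g1"])
    def test_malformed_raises(self, bad):
        with pytest.raises(ValueError):
            parse_gpr(bad)


class TestModelInvariants:
    def test_duplicate_species_rejected(self):
        model = MetabolicModel(compartments=["c"])
        model.add_species(Species(id="A", compartment="c"))
        with pytest.raises(ValueError, match="duplicate"):
            model.add_species(Species(id="A", compartment="c"))

    def test_undeclared_compartment_rejected(self):
        model = MetabolicModel(compartments=["c"])
        with pytest.raises(ValueError, match="undeclared compartment"):
            model.add_species(Species(id="A", compartment="x"))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            Reaction("r", {"A": -1.0}, 1.0, -1.0)

    def test_unknown_species_in_reaction_rejected(self):
        model = MetabolicModel(compartments=["c"])
        with pytest.raises(ValueError, match="unknown species"):
            model.add_reaction(Reaction("r", {"ghost": -1.0}))

    def test_empty_stoichiometry_needs_exchange_flag(self):
        model = MetabolicModel(compartments=["c"])
        with pytest.raises(ValueError, match="empty stoichiometry"):
            model.add_reaction(Reaction("r", {}))

    def test_pseudo_metabolite_gets_sbo_term(self):
        sp = Species(id="ES", compartment="c",
                     category=SpeciesCategory.PSEUDO_METABOLITE)
        assert sp.annotations["sbo"] == SBO_PSEUDO_METABOLITE

    def test_gene_set_is_union_of_gprs(self, fixture_model):
        union = set()
        for rxn in fixture_model.reactions:
            union |= rxn.genes
        assert fixture_model.genes == union

    def test_stoichiometric_matrix_shape(self, fixture_model):
        S = fixture_model.stoichiometric_matrix()
        assert S.shape == (
            len(fixture_model.species),
            len(fixture_model.reactions),
        )


class TestDeadEnds:
    def test_chain_reports_terminal_species(self):
        model = MetabolicModel(compartments=["c"])
        for sid in ("A", "B", "C"):
            model.add_species(Species(id=sid, compartment="c"))
        model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, is_exchange=True))
        model.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}))
        model.add_reaction(Reaction("R2", {"B": -1.0, "C": 1.0}))
        assert find_dead_ends(model) == ["C"]

    def test_cycled_scaffold_not_dead(self):
        model = MetabolicModel(compartments=["c"])
        for sid in ("ES", "SS"):
            model.add_species(
                Species(id=sid, compartment="c",
                        category=SpeciesCategory.PSEUDO_METABOLITE)
            )
        model.add_species(Species(id="don", compartment="c"))
        model.add_reaction(Reaction("EX_don", {"don": -1.0}, -1.0, 0.0, is_exchange=True))
        model.add_reaction(Reaction("LOAD", {"ES": -1.0, "don": -1.0, "SS": 1.0}))
        model.add_reaction(Reaction("RELEASE", {"SS": -1.0, "ES": 1.0}))
        assert find_dead_ends(model) == []

    def test_all_exchanged_model_has_none(self):
        model = MetabolicModel(compartments=["c"])
        for sid in ("A", "B"):
            model.add_species(Species(id=sid, compartment="c"))
            model.add_reaction(
                Reaction(f"EX_{sid}", {sid: -1.0}, -1.0, 1.0, is_exchange=True)
            )
        model.add_reaction(Reaction("R", {"A": -1.0, "B": 1.0}))
        assert find_dead_ends(model) == []

    def test_reversible_reaction_counts_both_ways(self):
        model = MetabolicModel(compartments=["c"])
        for sid in ("A", "B"):
            model.add_species(Species(id=sid, compartment="c"))
        model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 1.0, is_exchange=True))
        model.add_reaction(Reaction("R", {"A": -1.0, "B": 1.0}, -10.0, 10.0))
        assert find_dead_ends(model) == []

    def test_pseudo_exclusion_flag(self):
        model = MetabolicModel(compartments=["c"])
        model.add_species(
            Species(id="PS", compartment="c",
                    category=SpeciesCategory.PSEUDO_METABOLITE)
        )
        model.add_species(Species(id="A", compartment="c"))
        model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 1.0, is_exchange=True))
        model.add_reaction(Reaction("R", {"A": -1.0, "PS": 1.0}))
        assert find_dead_ends(model) == ["PS"]
        assert find_dead_ends(model, include_pseudo=False) == []

    def test_fixture_has_no_dead_ends(self, fixture_model):
        assert find_dead_ends(fixture_model) == []


class TestDiff:
    def test_self_diff_is_empty(self, fixture_model):
        diff = diff_models(fixture_model, fixture_model)
        assert diff.n_added_reactions == 0
        assert diff.n_removed_reactions == 0
        assert diff.n_modified_reactions == 0
        assert len(diff.matched_reactions) == len(fixture_model.reactions)

    def test_injected_reactions_counted(self, fixture_model):
        extended = fixture_model.copy()
        extended.add_species(Species(id="new_c", compartment="c"))
        for i in range(3):
            extended.add_reaction(Reaction(f"NEW_{i}", {"new_c": 1.0 if i else -1.0}))
        diff = diff_models(fixture_model, extended)
        assert diff.n_added_reactions == 3
        assert diff.added_species == ["new_c"]

    def test_modified_reaction_detected(self, fixture_model):
        other = fixture_model.copy()
        other.get_reaction("GLYC").stoichiometry["pyr_c"] = 3.0
        diff = diff_models(fixture_model, other)
        assert diff.modified_reactions == ["GLYC"]

    def test_swap_symmetry(self, fixture_model):
        extended = fixture_model.copy()
        extended.add_species(Species(id="new_c", compartment="c"))
        extended.add_reaction(Reaction("NEW", {"new_c": -1.0}))
        extended.remove_reaction("EX_pad") if extended.has_reaction("EX_pad") else None
        fwd = diff_models(fixture_model, extended)
        rev = diff_models(extended, fixture_model)
        assert fwd.added_reactions == rev.removed_reactions
        assert fwd.removed_reactions == rev.added_reactions

    def test_stoichiometry_fallback_matching(self):
        base = MetabolicModel(compartments=["c"])
        base.add_species(Species(id="A", compartment="c"))
        base.add_reaction(Reaction("old_name", {"A": -1.0}, -1.0, 1.0, is_exchange=True))
        ext = MetabolicModel(compartments=["c"])
        ext.add_species(Species(id="A", compartment="c"))
        ext.add_reaction(Reaction("new_name", {"A": -1.0}, -1.0, 1.0, is_exchange=True))
        strict = diff_models(base, ext)
        assert strict.n_added_reactions == 1 and strict.n_removed_reactions == 1
        fallback = diff_models(base, ext, match_by_stoichiometry=True)
        assert fallback.n_added_reactions == 0 and fallback.n_removed_reactions == 0


class TestSBMLRoundTrip:
    def _assert_equivalent(self, a, b):
        assert sorted(a.species_ids()) == sorted(b.species_ids())
        assert sorted(a.reaction_ids()) == sorted(b.reaction_ids())
        diff = diff_models(a, b)
        assert diff.n_modified_reactions == 0, diff.modified_reactions
        assert a.objective == b.objective
        for sp in a.species:
            other = b.get_species(sp.id)
            assert sp.category == other.category
            assert sp.compartment == other.compartment

    def test_fixture_round_trip(self, fixture_model, tmp_path):
        path = tmp_path / "fixture.xml"
        write_sbml(fixture_model, str(path))
        again = read_sbml(str(path))
        self._assert_equivalent(fixture_model, again)

    def test_double_round_trip_identical_bytes(self, fixture_model, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml(fixture_model, str(p1))
        write_sbml(read_sbml(str(p1)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_pseudo_metabolite_sbo_preserved(self, fixture_model, tmp_path):
        path = tmp_path / "fixture.xml"
        write_sbml(fixture_model, str(path))
        text = path.read_text()
        assert "SBO:0000409" in text
        again = read_sbml(str(path))
        es = again.get_species("ES_m")
        assert es.category == SpeciesCategory.PSEUDO_METABOLITE

    def test_literal_cofactor_round_trip(self, tmp_path):
        model = MetabolicModel(compartments=["c"], objective=None)
        for sid in ("A", "B", "X"):
            model.add_species(Species(id=sid, compartment="c"))
        rxn = Reaction("R", {"A": -1.0, "B": 1.0},
                       annotations={"cofactor:X": "1e-05"})
        rxn.stoichiometry["X"] = 0.0
        model.add_reaction(rxn)
        model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, is_exchange=True))
        model.add_reaction(Reaction("EX_B", {"B": -1.0}, 0.0, 1.0, is_exchange=True))
        path = tmp_path / "lit.xml"
        write_sbml(model, str(path))
        again = read_sbml(str(path))
        assert again.get_reaction("R").literal_cofactors() == {"X": 1e-05}
        assert again.get_reaction("R").stoichiometry.get("X", 0.0) == 0.0

    def test_empty_model_round_trip(self, tmp_path):
        model = MetabolicModel(model_id="empty", compartments=["c"])
        path = tmp_path / "empty.xml"
        write_sbml(model, str(path))
        again = read_sbml(str(path))
        assert again.species == [] and again.reactions == []

    def test_gpr_preserved(self, fixture_model, tmp_path):
        path = tmp_path / "fixture.xml"
        write_sbml(fixture_model, str(path))
        again = read_sbml(str(path))
        for rxn in fixture_model.reactions:
            assert again.get_reaction(rxn.id).gpr_string == rxn.gpr_string

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><unclosed></sbml>")
        with pytest.raises(ValueError, match="line"):
            read_sbml(str(path))

    def test_level2_cobra_notes_dialect(self, tmp_path):
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
  <model id="l2toy">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" initialAmount="0"/>
      <species id="B" compartment="c" initialAmount="0"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false">
        <notes><body xmlns="http://www.w3.org/1999/xhtml">
          <p>GENE_ASSOCIATION: g1 or g2</p>
        </body></notes>
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <ci>FLUX_VALUE</ci>
          </math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0"/>
            <parameter id="UPPER_BOUND" value="5"/>
            <parameter id="FLUX_VALUE" value="0"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        path = tmp_path / "l2.xml"
        path.write_text(text)
        model = read_sbml(str(path))
        rxn = model.get_reaction("R1")
        assert rxn.upper_bound == 5.0
        assert rxn.lower_bound == 0.0
        assert rxn.gpr_string == "g1 or g2"

    def test_missing_objective_error_instructs(self, tmp_path):
        model = MetabolicModel(compartments=["c"])
        model.add_species(Species(id="A", compartment="c"))
        model.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, is_exchange=True))
        path = tmp_path / "noobj.xml"
        write_sbml(model, str(path))
        with pytest.raises(ValueError, match="objective"):
            read_sbml(str(path), require_objective=True)
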