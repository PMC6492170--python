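import numpy as np
import pytest

from cofactorflux.cofactor_augmentation import (
    AffinityThreshold,
    ClusterSpec,
    CofactorRequirement,
    RegulonConfig,
    ScaffoldConfig,
    ScaffoldRoute,
    augment_model,
    augment_reaction,
    build_regulon_circuit,
    build_scaffold_cycle,
    couple_haem_to_low_affinity,
    drain_reaction_id,
    spent_species_id,
    threshold_to_bound,
)
from cofactorflux.essentiality import delete_gene
from cofactorflux.fixtures import FixtureConfig, cofactor_table, generate_fixture
from cofactorflux.lp_engine import optimize_growth
from cofactorflux.model_core import MetabolicModel, Reaction, Species


@pytest.fixture()
def unaugmented_model():
    """Fixture topology with zero cofactor coefficients (no augmentation)."""
    model, _ = generate_fixture(FixtureConfig(cofactor_magnitude=0.0))
    return model


def _with_free_cofactor(model, bound=1000.0):
    """Attach a cofactor species with its own unconstrained supply."""
    out = model.copy()
    out.add_species(Species(id="zn_c", name="free cofactor", compartment="c"))
    out.add_reaction(
        Reaction("EX_zn", {"zn_c": -1.0}, -bound, 0.0, is_exchange=True)
    )
    return out


class TestAugmentReaction:
    def test_free_to_spent_splits_pools(self, unaugmented_model):
        model = _with_free_cofactor(unaugmented_model)
        req = CofactorRequirement("RESP", "zn_c", 1e-3)
        augment_reaction(model, req)
        rxn = model.get_reaction("RESP")
        assert rxn.stoichiometry["zn_c"] == pytest.approx(-1e-3)
        assert rxn.stoichiometry[spent_species_id("zn_c")] == pytest.approx(1e-3)
        assert model.has_reaction(drain_reaction_id("zn_c"))

    def test_literal_mode_records_annotation_only(self, unaugmented_model):
        model = unaugmented_model.copy()
        before = dict(model.get_reaction("RESP").stoichiometry)
        req = CofactorRequirement("RESP", "haem_m", 1e-14,
                                  mode="literal_both_sides")
        augment_reaction(model, req)
        rxn = model.get_reaction("RESP")
        assert rxn.literal_cofactors() == {"haem_m": 1e-14}
        net = {k: v for k, v in rxn.stoichiometry.items() if v != 0.0}
        assert net == before

    def test_zero_coefficient_changes_annotation_only(self, unaugmented_model):
        model = unaugmented_model.copy()
        before = dict(model.get_reaction("RESP").stoichiometry)
        augment_reaction(model, CofactorRequirement("RESP", "haem_m", 0.0))
        rxn = model.get_reaction("RESP")
        assert rxn.stoichiometry == before
        assert "cofactor_requirement:haem_m" in rxn.annotations
        assert not model.has_species(spent_species_id("haem_m"))

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            CofactorRequirement("RESP", "haem_m", -1.0)

    def test_missing_cofactor_species_rejected(self, unaugmented_model):
        with pytest.raises(KeyError, match="ghost"):
            augment_reaction(
                unaugmented_model.copy(), CofactorRequirement("RESP", "ghost", 1e-3)
            )


class TestAugmentModel:
    def test_empty_table_is_identity(self, unaugmented_model):
        out = augment_model(unaugmented_model, [])
        assert sorted(out.reaction_ids()) == sorted(unaugmented_model.reaction_ids())
        assert optimize_growth(out).objective_value == pytest.approx(
            optimize_growth(unaugmented_model).objective_value, rel=1e-10
        )

    def test_three_rows_two_cofactors(self, unaugmented_model):
        table = [
            CofactorRequirement("RESP", "haem_m", 1e-5),
            CofactorRequirement("RESP", "fes_m", 1e-5),
            CofactorRequirement("HAEM_SYN", "fes_m", 5e-6),
        ]
        out = augment_model(unaugmented_model, table)
        spent = [s.id for s in out.species if "spent_pool_of" in s.annotations]
        assert sorted(spent) == ["fes_m__spent", "haem_m__spent"]
        for rid in ("RESP", "HAEM_SYN"):
            assert any(k.startswith("cofactor_requirement:")
                       for k in out.get_reaction(rid).annotations)

    def test_duplicate_rows_rejected_and_listed(self, unaugmented_model):
        table = [
            CofactorRequirement("RESP", "haem_m", 1e-5),
            CofactorRequirement("RESP", "haem_m", 2e-5),
        ]
        with pytest.raises(ValueError, match="RESP"):
            augment_model(unaugmented_model, table)

    def test_nonbinding_supply_preserves_optimum(self, unaugmented_model):
        base = _with_free_cofactor(unaugmented_model)
        augmented = augment_model(
            base, [CofactorRequirement("RESP", "zn_c", 1e-3)]
        )
        g0 = optimize_growth(base).objective_value
        g1 = optimize_growth(augmented).objective_value
        assert g1 == pytest.approx(g0, rel=1e-8)

    def test_literal_table_preserves_optimum(self, unaugmented_model):
        table = [
            CofactorRequirement(r.reaction_id, r.cofactor_species_id,
                                r.coefficient, mode="literal_both_sides")
            for r in cofactor_table(FixtureConfig())
        ]
        augmented = augment_model(unaugmented_model, table)
        g0 = optimize_growth(unaugmented_model).objective_value
        g1 = optimize_growth(augmented).objective_value
        assert g1 == pytest.approx(g0, rel=1e-10)

    def test_binding_supply_strictly_reduces_growth(self, unaugmented_model):
        base = _with_free_cofactor(unaugmented_model, bound=2e-4)
        augmented = augment_model(
            base, [CofactorRequirement("RESP", "zn_c", 1e-3)]
        )
        g0 = optimize_growth(base).objective_value
        g1 = optimize_growth(augmented).objective_value
        assert g1 < 0.5 * g0  # supply 2e-4 vs demand 1e-3 per unit respiration

    def test_binding_iron_bound_reduces_growth(self):
        tight, _ = generate_fixture(FixtureConfig(iron_exchange_bound=2e-5))
        base, _ = generate_fixture(FixtureConfig(cofactor_magnitude=0.0))
        g_tight = optimize_growth(tight).objective_value
        g_base = optimize_growth(base).objective_value
        assert g_tight < g_base * 0.5

    def test_growth_monotone_in_coefficient(self, unaugmented_model):
        base = _with_free_cofactor(unaugmented_model, bound=1e-3)
        previous = np.inf
        for x in (0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2):
            table = [CofactorRequirement("RESP", "zn_c", x)] if x else []
            g = optimize_growth(augment_model(base, table)).objective_value
            assert g <= previous + 1e-9
            previous = g


class TestScaffoldCycle:
    def _bare_model(self):
        model = MetabolicModel(compartments=["m"], objective="DM_fes")
        for sid in ("don_m", "fe_m", "fes_x")[0:3]:
            model.add_species(Species(id=sid, compartment="m"))
        model.add_reaction(
            Reaction("EX_don", {"don_m": -1.0}, -10.0, 0.0, is_exchange=True)
        )
        model.add_reaction(
            Reaction("EX_fe", {"fe_m": -1.0}, -10.0, 0.0, is_exchange=True)
        )
        model.add_reaction(Reaction("DM_fes", {"fes_x": -1.0}, 0.0, 5.0,
                                    is_exchange=True))
        return model

    def _config(self, routes=None):
        return ScaffoldConfig(
            sulphur_donor="don_m",
            iron_species="fe_m",
            compartment="m",
            es_id="ES",
            ss_id="SS",
            clusters=[ClusterSpec("fes_x", iron_stoichiometry=4.0,
                                  routes=routes or [ScaffoldRoute()])],
        )

    def test_moiety_is_left_null_vector_of_added_columns(self):
        model = build_scaffold_cycle(self._bare_model(), self._config())
        S = model.stoichiometric_matrix().toarray()
        sids = model.species_ids()
        indicator = np.zeros(len(sids))
        indicator[sids.index("ES")] = 1.0
        indicator[sids.index("SS")] = 1.0
        for rid in ("SCAFFOLD_LOAD_fes_x", "SCAFFOLD_RELEASE_fes_x"):
            j = model.reaction_ids().index(rid)
            assert indicator @ S[:, j] == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_couples_load_and_release(self):
        model = build_scaffold_cycle(self._bare_model(), self._config())
        sol = optimize_growth(model)
        assert sol.optimal
        assert sol.fluxes["SCAFFOLD_LOAD_fes_x"] == pytest.approx(
            sol.fluxes["SCAFFOLD_RELEASE_fes_x"], abs=1e-9
        )
        assert sol.fluxes["SCAFFOLD_RELEASE_fes_x"] == pytest.approx(2.5, abs=1e-8)

    def test_blocking_load_zeroes_cluster_production(self):
        model = build_scaffold_cycle(self._bare_model(), self._config())
        model.get_reaction("SCAFFOLD_LOAD_fes_x").upper_bound = 0.0
        sol = optimize_growth(model)
        assert sol.fluxes["SCAFFOLD_RELEASE_fes_x"] == pytest.approx(0.0, abs=1e-10)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_two_maturation_routes_give_two_release_reactions(self):
        routes = [ScaffoldRoute("lip5_sdh2", "g_lip5 or g_sdh2"),
                  ScaffoldRoute("other", "g_other")]
        model = build_scaffold_cycle(self._bare_model(), self._config(routes))
        assert model.has_reaction("SCAFFOLD_RELEASE_fes_x_lip5_sdh2")
        assert model.has_reaction("SCAFFOLD_RELEASE_fes_x_other")
        assert model.get_reaction(
            "SCAFFOLD_RELEASE_fes_x_lip5_sdh2"
        ).gpr_string == "g_lip5 or g_sdh2"

    def test_missing_donor_rejected(self):
        config = self._config()
        config.sulphur_donor = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            build_scaffold_cycle(self._bare_model(), config)


class TestRegulonCircuit:
    def test_requires_scaffold(self):
        with pytest.raises(ValueError, match="regulon without.*scaffold|scaffold"):
            generate_fixture(
                FixtureConfig(include_scaffold=False, include_regulon=True)
            )

    def test_build_requires_scaffold_reactions(self, unaugmented_model):
        bare, _ = generate_fixture(
            FixtureConfig(include_scaffold=False, include_regulon=False)
        )
        with pytest.raises(ValueError, match="scaffold"):
            build_regulon_circuit(
                bare, RegulonConfig(high_affinity_uptake_reactions=["FE_HIGH"])
            )

    def test_unknown_uptake_reaction_rejected(self, unaugmented_model):
        base, _ = generate_fixture(
            FixtureConfig(include_scaffold=True, include_regulon=False)
        )
        with pytest.raises(KeyError, match="GHOST"):
            build_regulon_circuit(
                base, RegulonConfig(high_affinity_uptake_reactions=["GHOST"])
            )

    def test_abundant_low_affinity_iron_idles_high_affinity(self, fixture_model):
        sol = optimize_growth(fixture_model)
        assert sol.fluxes["FE_HIGH"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["SIG_BRANCH_AS"] == pytest.approx(0.0, abs=1e-9)

    def test_blocked_low_affinity_routes_through_high_affinity(self, fixture_model):
        model = fixture_model.copy()
        model.get_reaction("FE_LOW").upper_bound = 0.0
        sol = optimize_growth(model)
        assert sol.optimal and sol.objective_value > 0.9
        assert sol.fluxes["FE_LOW"] == 0.0
        assert sol.fluxes["FE_HIGH"] == pytest.approx(-sol.fluxes["EX_fe3"],
                                                      rel=1e-6)
        assert sol.fluxes["SIG_BRANCH_AS"] > 0.0

    def test_circuit_neutral_when_nonbinding(self):
        with_circuit, _ = generate_fixture(FixtureConfig(include_regulon=True))
        without, _ = generate_fixture(FixtureConfig(include_regulon=False))
        a = optimize_growth(with_circuit)
        b = optimize_growth(without)
        for rid in ("GROWTH", "EX_glc", "EX_o2", "EX_fe3", "RESP"):
            assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], rel=1e-8,
                                                  abs=1e-10), rid


class TestHaemCoupling:
    def test_haem_gene_deletion_closes_low_affinity_and_reroutes(self, fixture_model):
        # strip the haem cofactor requirement so haem genes only matter
        # for the uptake coupling, then delete one of them
        model = fixture_model.copy()
        resp = model.get_reaction("RESP")
        for sid in ("haem_m", "haem_m__spent"):
            resp.stoichiometry.pop(sid, None)
        deleted = delete_gene(model, "g_hem1")
        assert deleted.get_reaction("FE_LOW").upper_bound == 0.0
        sol = optimize_growth(deleted)
        assert sol.optimal and sol.objective_value > 0.9
        assert sol.fluxes["FE_HIGH"] > 0.0

    def test_empty_gene_list_leaves_gpr_unchanged(self, fixture_model):
        before = fixture_model.get_reaction("FE_LOW").gpr_string
        out = couple_haem_to_low_affinity(fixture_model, [], "FE_LOW")
        assert out.get_reaction("FE_LOW").gpr_string == before

    def test_all_genes_present_keeps_uptake_available(self, fixture_model):
        rxn = fixture_model.get_reaction("FE_LOW")
        assert rxn.gpr.evaluate(set())
        sol = optimize_growth(fixture_model)
        assert sol.fluxes["FE_LOW"] > 0.0


class TestAffinityThreshold:
    def test_iron_micromolar_conversion(self):
        th = AffinityThreshold("iron", 1.0, 1e-3)
        assert threshold_to_bound(th) == pytest.approx(1e-3)
        assert th.derived_flux_bound == pytest.approx(1e-3)

    def test_copper_twenty_micromolar(self):
        th = AffinityThreshold("copper", 20.0, 1e-3)
        assert threshold_to_bound(th) == pytest.approx(2e-2)

    def test_zero_conversion_factor_rejected(self):
        with pytest.raises(ValueError):
            threshold_to_bound(AffinityThreshold("iron", 1.0, 0.0))

    def test_unknown_ion_rejected(self):
        with pytest.raises(ValueError):
            AffinityThreshold("cobalt", 1.0, 1e-3)
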