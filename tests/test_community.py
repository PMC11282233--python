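import pytest

import commflux as cf
from commflux.fba import steady_state_residual
from commflux.model import ModelValidationError

from conftest import to_cobra

COMM_MEDIA = cf.Media("glc", {"EX_glc_e0": 10.0})


class TestTagNamespace:
    def test_internal_ids_suffixed_extracellular_pooled(self, toy_a):
        tagged = cf.tag_namespace(toy_a, "a")
        assert "glc_c_a" in tagged.metabolites
        assert "glc_e0" in tagged.metabolites
        assert tagged.metabolites["glc_e0"].compartment == "e0"
        assert "EX_glc" not in tagged.reactions  # member exchanges removed
        assert tagged.reactions["T_glc_a"].stoichiometry == {
            "glc_e0": -1.0, "glc_c_a": 1.0}

    def test_bad_tag_rejected(self, toy_a):
        for tag in ("", "a_b", "a b", "a:b"):
            with pytest.raises(ValueError):
                cf.tag_namespace(toy_a, tag)

    def test_no_extracellular_pure_suffixing(self):
        model = cf.MetabolicModel("inner", metabolites=[
            cf.Metabolite("x_c", compartment="c"), cf.Metabolite("y_c", compartment="c")])
        model.add_reaction(cf.Reaction("R", {"x_c": -1.0, "y_c": 1.0}, 0, 10))
        tagged = cf.tag_namespace(model, "t")
        assert set(tagged.metabolites) == {"x_c_t", "y_c_t"}
        assert set(tagged.reactions) == {"R_t"}


class TestMergeModels:
    def test_reaction_ledger(self, toy_a, toy_b):
        """(6-2) + (5-2) member reactions + 3 community exchanges = 10."""
        community = cf.merge_models([toy_a, toy_b], ["a", "b"])
        assert len(community.reactions) == 10
        assert {r.id for r in community.exchanges} == {
            "EX_glc_e0", "EX_ac_e0", "EX_but_e0"}
        assert community.community_biomass_id is None

    def test_shared_pool_metabolites_deduplicated(self, toy_community):
        # ToyA secretes acetate, ToyB consumes it: one shared ac_e0 row
        assert "ac_e0" in toy_community.metabolites
        assert "ac_e0_a" not in toy_community.metabolites

    def test_biomass_species_have_no_exchange(self, toy_community):
        assert "EX_biomass_a" not in toy_community.reactions
        assert "EX_biomass_a_e0" not in toy_community.reactions
        assert toy_community.reactions["BIOMASS_a"].stoichiometry["biomass_a"] == 1.0

    def test_single_member_rejected(self, toy_a):
        with pytest.raises(ValueError):
            cf.merge_models([toy_a], ["a"])

    def test_duplicate_tags_rejected(self, toy_a, toy_b):
        with pytest.raises(ValueError):
            cf.merge_models([toy_a, toy_b], ["a", "a"])


class TestCommunityBiomass:
    def test_coefficients_are_abundances(self, toy_community):
        profile = cf.AbundanceProfile("healthy", {"a": 0.5, "b": 0.5})
        community = cf.add_community_biomass(toy_community, profile)
        stoich = community.reactions["CBIOMASS"].stoichiometry
        assert stoich == {"biomass_a": -0.5, "biomass_b": -0.5}
        assert community.objective_id == "CBIOMASS"

    def test_all_zero_rejected(self, toy_community):
        with pytest.raises(ModelValidationError):
            cf.add_community_biomass(
                toy_community, cf.AbundanceProfile("z", {"a": 0.0, "b": 0.0}))

    def test_single_member_community_equals_member_alone(self, toy_a, toy_community):
        """Abundance (1, 0): the community grows exactly as the member would."""
        community = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("only_a", {"a": 1.0}))
        z_comm = cf.optimize(cf.apply_media(community, COMM_MEDIA)).objective_value
        z_alone = cf.optimize(
            cf.apply_media(toy_a, cf.Media("glc", {"EX_glc": 10.0}))).objective_value
        assert z_comm == pytest.approx(z_alone, abs=1e-6)

    def test_growth_matches_glpk_oracle(self, toy_community):
        community = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("even", {"a": 0.5, "b": 0.5}))
        fed = cf.apply_media(community, COMM_MEDIA)
        mine = cf.optimize(fed).objective_value
        oracle = to_cobra(fed).slim_optimize()
        assert mine == pytest.approx(oracle, abs=1e-6)
        # glc 10 -> 10 biomass_a + 20 acetate -> 10 biomass_b; 0.5 each per unit
        assert mine == pytest.approx(20.0, abs=1e-6)

    def test_abundance_scaling_inverse(self, toy_community):
        """Scaling all a_k by c scales the community optimum by 1/c."""
        base = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("p", {"a": 0.3, "b": 0.7}))
        z1 = cf.optimize(cf.apply_media(base, COMM_MEDIA)).objective_value
        for c in (0.5, 2.0, 10.0):
            scaled = cf.add_community_biomass(
                toy_community,
                cf.AbundanceProfile("p", {"a": 0.3 * c, "b": 0.7 * c}))
            z_c = cf.optimize(cf.apply_media(scaled, COMM_MEDIA)).objective_value
            assert z_c == pytest.approx(z1 / c, rel=1e-8)

    def test_member_block_steady_state(self, toy_community):
        """A community-optimal flux restricted to one member is still balanced."""
        community = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("even", {"a": 0.5, "b": 0.5}))
        fed = cf.apply_media(community, COMM_MEDIA)
        state = cf.optimize(fed)
        assert steady_state_residual(fed, state) <= 1e-6
        for tag in ("a", "b"):
            member_rxns = {r.id for r in fed.member_reactions(tag)}
            for met_id, met in fed.metabolites.items():
                if met.compartment == "e0":
                    continue
                if not met_id.endswith(f"_{tag}"):
                    continue
                net = sum(
                    coeff * state[rid]
                    for rid in member_rxns
                    for m2, coeff in fed.reactions[rid].stoichiometry.items()
                    if m2 == met_id
                )
                assert abs(net) <= 1e-6


class TestApplyCondition:
    def test_conditions_differ_only_in_cbiomass(self, toy_community):
        healthy = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("healthy", {"a": 0.5, "b": 0.5}))
        disease = cf.apply_condition(
            healthy, cf.AbundanceProfile("disease", {"a": 0.5, "b": 0.25}))
        assert disease.reactions["CBIOMASS"].stoichiometry == {
            "biomass_a": -0.5, "biomass_b": -0.25}
        for rid in healthy.reactions:
            if rid != "CBIOMASS":
                assert disease.reactions[rid] == healthy.reactions[rid]

    def test_reapplication_idempotent(self, toy_community):
        profile = cf.AbundanceProfile("h", {"a": 0.4, "b": 0.6})
        once = cf.add_community_biomass(toy_community, profile)
        twice = cf.apply_condition(once, profile)
        assert twice == once

    def test_unknown_tag_rejected(self, toy_community):
        healthy = cf.add_community_biomass(
            toy_community, cf.AbundanceProfile("h", {"a": 1.0}))
        with pytest.raises(ModelValidationError, match="ghost"):
            cf.apply_condition(healthy, cf.AbundanceProfile("d", {"ghost": 1.0}))

    def test_before_biomass_rejected(self, toy_community):
        with pytest.raises(ModelValidationError):
            cf.apply_condition(toy_community, cf.AbundanceProfile("h", {"a": 1.0}))


class TestAbundanceIO:
    def test_round_trip(self, tmp_path):
        profiles = {
            "healthy": cf.AbundanceProfile("healthy", {"a": 0.5, "b": 0.5}),
            "disease": cf.AbundanceProfile("disease", {"a": 0.7, "b": 0.1}),
        }
        path = tmp_path / "ab.tsv"
        from commflux.community import write_abundances
        write_abundances(profiles, path)
        again = cf.read_abundances(path)
        assert again.keys() == profiles.keys()
        for cond in profiles:
            assert again[cond].abundances == profiles[cond].abundances
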