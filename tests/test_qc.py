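import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import commflux as cf
from commflux.model import Metabolite, Reaction
from commflux.qc import check_balance, rebalance_protons

from conftest import to_cobra

GLC = {"C": 6, "H": 12, "O": 6}
AC = {"C": 2, "H": 4, "O": 2}


def _mets(**formulas):
    return {
        mid: Metabolite(mid, compartment="c", formula=dict(f) if f else {},
                        charge=charge)
        for mid, (f, charge) in formulas.items()
    }


class TestCheckBalance:
    def test_carbon_loss_detected(self):
        mets = _mets(glc_c=(GLC, 0), ac_c=(AC, 0))
        rxn = Reaction("BAD", {"glc_c": -1.0, "ac_c": 2.0})
        result = check_balance(rxn, mets)
        assert result.status == "imbalanced"
        assert result.element_imbalance == {"C": -2.0, "H": -4.0, "O": -2.0}

    def test_identity_conversion_balanced(self):
        mets = _mets(a_c=({"C": 1, "H": 4}, 0), b_c=({"C": 1, "H": 4}, 0))
        result = check_balance(Reaction("ISO", {"a_c": -1.0, "b_c": 1.0}), mets)
        assert result.status == "balanced"
        assert result.element_imbalance == {}
        assert result.charge_imbalance == 0.0

    def test_missing_formula_is_indeterminate(self):
        mets = _mets(a_c=({"C": 1}, 0), b_c=(None, None))
        result = check_balance(Reaction("R", {"a_c": -1.0, "b_c": 1.0}), mets)
        assert result.status == "indeterminate"

    def test_exchange_and_biomass_exempt(self):
        mets = _mets(a_c=(GLC, 0))
        rxn = Reaction("EX_a", {"a_c": -1.0}, is_exchange=True)
        assert check_balance(rxn, mets).status == "exempt"
        rxn2 = Reaction("GROW", {"a_c": -1.0})
        assert check_balance(rxn2, mets, objective_id="GROW").status == "exempt"

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(min_value=0.1, max_value=10, allow_nan=False))
    def test_linearity_in_coefficients(self, scale):
        """Scaling every coefficient by c scales every imbalance by c."""
        mets = _mets(glc_c=(GLC, 0), ac_c=(AC, 0))
        base = check_balance(Reaction("B", {"glc_c": -1.0, "ac_c": 2.0}), mets)
        scaled = check_balance(
            Reaction("B", {"glc_c": -scale, "ac_c": 2.0 * scale}), mets)
        for el, v in base.element_imbalance.items():
            assert scaled.element_imbalance[el] == pytest.approx(v * scale)


class TestRebalanceProtons:
    MET_KW = dict(
        a_c=({"C": 1, "H": 3}, 0), b_c=({"C": 1, "H": 4}, 1),
        h_c=({"H": 1}, 1),
    )

    def test_pure_proton_imbalance_fixed(self):
        mets = _mets(**self.MET_KW)
        rxn = Reaction("R", {"a_c": -1.0, "b_c": 1.0})  # +1 H, +1 charge
        fixed = rebalance_protons(rxn, mets, "h_c")
        assert fixed is not None
        assert check_balance(fixed, mets).status == "balanced"
        assert fixed.stoichiometry["h_c"] == -1.0
        assert rxn.stoichiometry == {"a_c": -1.0, "b_c": 1.0}  # input untouched

    def test_non_proton_imbalance_refused(self):
        mets = _mets(glc_c=(GLC, 0), ac_c=(AC, 0), h_c=({"H": 1}, 1))
        assert rebalance_protons(
            Reaction("R", {"glc_c": -1.0, "ac_c": 2.0}), mets, "h_c") is None

    def test_balanced_returned_unchanged(self):
        mets = _mets(a_c=({"C": 1, "H": 4}, 0), b_c=({"C": 1, "H": 4}, 0),
                     h_c=({"H": 1}, 1))
        rxn = Reaction("R", {"a_c": -1.0, "b_c": 1.0})
        assert rebalance_protons(rxn, mets, "h_c") == rxn

    def test_missing_proton_errors(self):
        mets = _mets(a_c=({"C": 1}, 0))
        with pytest.raises(KeyError):
            rebalance_protons(Reaction("R", {"a_c": -1.0}), mets, "h_c")


class TestUnboundReactions:
    def test_two_cycle_flagged_at_upper_bound(self, broken):
        flagged = cf.find_unbound_reactions(broken["tic"])
        assert flagged == [("LOOPF", 1000.0), ("LOOPR", 1000.0)]

    def test_clean_model_empty(self, toy_a):
        assert cf.find_unbound_reactions(toy_a) == []

    def test_three_cycle_matches_oracle(self):
        """All three loop reactions hit the bound; verified against GLPK FVA."""
        mets = [Metabolite(m, compartment="c") for m in ("a_c", "b_c", "c_c")]
        model = cf.MetabolicModel("cycle3", metabolites=mets)
        model.add_reaction(Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0))
        model.add_reaction(Reaction("R2", {"b_c": -1.0, "c_c": 1.0}, 0.0, 1000.0))
        model.add_reaction(Reaction("R3", {"c_c": -1.0, "a_c": 1.0}, 0.0, 1000.0))
        model.objective_id = "R3"
        flagged = cf.find_unbound_reactions(model)
        assert [rid for rid, _ in flagged] == ["R1", "R2", "R3"]

        from cobra.flux_analysis import flux_variability_analysis
        oracle = flux_variability_analysis(to_cobra(model), fraction_of_optimum=0.0,
                                           processes=1)
        for rid, bound in flagged:
            assert oracle.loc[rid, "maximum"] == pytest.approx(bound, abs=1e-6)


class TestDeadEnds:
    def test_only_produced(self):
        mets = [Metabolite("x_c", compartment="c"), Metabolite("y_c", compartment="c")]
        model = cf.MetabolicModel("m", metabolites=mets)
        model.add_reaction(Reaction("R1", {"y_c": -1.0, "x_c": 1.0}, 0.0, 10.0))
        found = dict(cf.find_dead_end_metabolites(model))
        assert found["x_c"] == "only-produced"
        assert found["y_c"] == "only-consumed"

    def test_reversible_pair_not_flagged(self):
        mets = [Metabolite("x_c", compartment="c"), Metabolite("y_c", compartment="c")]
        model = cf.MetabolicModel("m", metabolites=mets)
        model.add_reaction(Reaction("R1", {"y_c": -1.0, "x_c": 1.0}, -10.0, 10.0))
        assert cf.find_dead_end_metabolites(model) == []

    def test_orphan(self, broken):
        assert cf.find_dead_end_metabolites(broken["dead_end"]) == [("unused_c", "orphan")]


class TestBlockedReactions:
    def test_missing_sink_blocks_whole_chain(self, toy_a, glc_media):
        """Without an acetate outlet the fermentation chain cannot run at all."""
        toy_a.remove_reaction("EX_ac")
        blocked = cf.find_blocked_reactions(toy_a, glc_media)
        assert blocked == ["BIOMASS", "EX_glc", "FERM", "T_ac", "T_glc"]

    def test_intact_toy_unblocked(self, toy_a, glc_media):
        assert cf.find_blocked_reactions(toy_a, glc_media) == []

    def test_smaller_media_blocks_superset(self, broken, glc_media):
        model = broken["blocked"]
        rich = cf.Media("rich", {"EX_glc": 10.0, "EX_rib": 5.0})
        blocked_rich = set(cf.find_blocked_reactions(model, rich))
        blocked_poor = set(cf.find_blocked_reactions(model, glc_media))
        assert blocked_rich <= blocked_poor


class TestQCReport:
    def test_clean_toy(self, toy_a, glc_media):
        assert cf.qc_report(toy_a, glc_media).clean

    def test_combined_defects_found_exactly(self, glc_media):
        """A TIC + an imbalanced reaction + an orphan: three findings, no more."""
        model = cf.make_broken_fixtures()["imbalanced"]
        model.add_metabolite(Metabolite("x1_c", compartment="c"))
        model.add_metabolite(Metabolite("x2_c", compartment="c"))
        model.add_reaction(Reaction("LOOPF", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0))
        model.add_reaction(Reaction("LOOPR", {"x2_c": -1.0, "x1_c": 1.0}, 0.0, 1000.0))
        model.add_metabolite(Metabolite("orph_c", compartment="c"))
        report = cf.qc_report(model, glc_media)
        assert [rid for rid, _, _ in report.imbalanced] == ["BADFERM"]
        assert [rid for rid, _ in report.unbound] == ["LOOPF", "LOOPR"]
        assert report.dead_end == [("orph_c", "orphan")]
        assert report.blocked == []
        assert report.gap_candidates == []

    def test_tsv_stable(self, tmp_path, glc_media):
        model = cf.make_broken_fixtures()["tic"]
        report = cf.qc_report(model, glc_media)
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        report.to_tsv(p1)
        cf.qc_report(model, glc_media).to_tsv(p2)
        assert p1.read_text() == p2.read_text()
        assert "unbound\tLOOPF" in p1.read_text()
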