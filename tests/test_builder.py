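"""Rate-law synthesis and model assembly."""

import pytest
import sympy as sp

from kintext import (
    ConflictError,
    NotSupportedError,
    SpeciesRef,
    StatementKind,
    build_model,
    make_rate_law,
    model_summary,
    split_reversible,
    translate,
)
from kintext.builder import Parameter
from kintext.ir import Quantity, ReactionStatement

K = StatementKind
S = sp.Symbol


def _ident(name):
    return name


class TestMakeRateLaw:
    def test_degradation_is_first_order_mass_action(self):
        stmt = ReactionStatement(K.DEGRADATION, substrates=[SpeciesRef("P")])
        rate, params, mods = make_rate_law(stmt, 1, _ident)
        assert rate.expression == S("k1") * S("P")
        assert params == [Parameter("k1", 1.0)] and mods == []

    def test_catalyzed_conversion_is_michaelis_menten(self):
        stmt = ReactionStatement(K.CONVERSION, substrates=[SpeciesRef("S")],
                                 products=[SpeciesRef("M1")], catalysts=["E1"])
        rate, params, mods = make_rate_law(stmt, 1, _ident)
        assert rate.expression == S("kcat1") * S("E1") * S("S") / (S("Km1") + S("S"))
        assert {p.id for p in params} == {"kcat1", "Km1"} and mods == ["E1"]

    def test_dimerization_forward_rate_is_quadratic(self):
        # mass-action oracle: rate = kf * M^stoich with stoich = 2
        stmt = ReactionStatement(K.BINDING, substrates=[SpeciesRef("M", 2)],
                                 products=[SpeciesRef("E")], reversible=True)
        reactions, _ = split_reversible(stmt, 1, _ident)
        assert reactions[0].rate.expression == S("kf1") * S("M") ** 2
        assert reactions[1].rate.expression == S("kr1") * S("E")

    def test_all_new_parameters_default_to_one(self):
        stmt = ReactionStatement(K.CONVERSION, substrates=[SpeciesRef("A")],
                                 products=[SpeciesRef("B")])
        _, params, _ = make_rate_law(stmt, 7, _ident)
        assert all(p.value == 1.0 for p in params)

    def test_regulated_synthesis_gets_hill_factors(self):
        stmt = ReactionStatement(K.SYNTHESIS, products=[SpeciesRef("X")])
        rate, params, mods = make_rate_law(
            stmt, 3, _ident, regulators=[("R", "repression")])
        R, Kh = S("R"), S("K3_R")
        assert rate.expression == S("v3") * Kh**2 / (Kh**2 + R**2)
        assert mods == ["R"]


class TestSplitReversible:
    def test_forward_and_backward_reactions(self):
        stmt = ReactionStatement(K.BINDING,
                                 substrates=[SpeciesRef("E"), SpeciesRef("S")],
                                 products=[SpeciesRef("ES")], reversible=True)
        (fwd, bwd), params = split_reversible(stmt, 2, _ident)
        assert (fwd.id, bwd.id) == ("J2_f", "J2_r")
        assert fwd.rate.expression == S("kf2") * S("E") * S("S")
        assert bwd.rate.expression == S("kr2") * S("ES")
        assert {p.id for p in params} == {"kf2", "kr2"}

    def test_irreversible_input_is_rejected(self):
        stmt = ReactionStatement(K.CONVERSION, substrates=[SpeciesRef("A")],
                                 products=[SpeciesRef("B")])
        with pytest.raises(NotSupportedError):
            split_reversible(stmt, 1, _ident)


class TestBuildModel:
    def test_empty_statement_list_gives_empty_model(self):
        assert model_summary(build_model([])) == (0, 0, 0)

    def test_decay_model(self, models):
        m = models["decay"]
        assert model_summary(m)[:2] == (1, 1)
        assert m.species[0].id == "P"
        assert m.species[0].initial_value == 1.0 and m.species[0].unit == "uM"

    def test_hiv_model_counts(self, models):
        assert model_summary(models["hiv"])[:2] == (9, 10)

    def test_three_step_model_counts(self, models):
        assert model_summary(models["three_step"])[:2] == (10, 15)

    def test_heat_shock_model_counts(self, models):
        assert model_summary(models["heat_shock"])[:2] == (25, 50)

    def test_three_step_structure(self, models):
        m = models["three_step"]
        assert set(m.species_ids()) == {
            "S", "M1", "M2", "P", "E1", "E2", "E3",
            "mRNA_E1", "mRNA_E2", "mRNA_E3"}
        # three Michaelis-Menten metabolic steps with enzymes as modifiers
        mm = [r for r in m.reactions if r.modifiers and r.reactants
              and r.reactants[0].name in ("S", "M1", "M2")]
        assert [r.modifiers for r in mm] == [["E1"], ["E2"], ["E3"]]
        # the repression of E3 appears as a modifier on its transcription only
        tx_e3 = next(r for r in m.reactions if r.products
                     and r.products[0].name == "mRNA_E3")
        assert tx_e3.modifiers == ["P"]

    def test_duplicate_initial_concentration_conflicts(self):
        text = "Protein P decays. P concentration is 1 uM. P concentration is 2 uM."
        with pytest.raises(ConflictError):
            build_model(translate(text))

    def test_reaction_count_equals_irreversible_plus_twice_reversible(self, problems):
        # brute-force recount oracle straight from the statement list
        for p in problems.values():
            stmts = translate(p.description)
            expected = sum(
                2 if s.reversible else (4 if s.kind is K.EXPRESSION else 1)
                for s in stmts
                if s.kind not in (K.INITIAL_CONCENTRATION, K.REGULATION, K.CATALYSIS))
            assert len(p.build().reactions) == expected == p.expected_reactions

    def test_parameters_are_local_to_one_rate_law(self, models):
        for m in models.values():
            used_by = {p.id: 0 for p in m.parameters}
            for r in m.reactions:
                for sym in r.rate.symbols():
                    if sym in used_by:
                        used_by[sym] += 1
            assert all(count == 1 for count in used_by.values())

    def test_build_is_invariant_to_delimiter_variants(self, problems):
        from kintext import models_equivalent
        text = problems["decay"].description
        variants = [text, text.strip(), text.replace(". ", ".  ") + "  "]
        built = [build_model(translate(t)) for t in variants]
        assert all(models_equivalent(built[0], b) for b in built[1:])

    def test_sigma32_transliteration_in_heat_shock(self, models):
        sids = set(models["heat_shock"].species_ids())
        assert "sigma32" in sids and "sigma70" in sids
        assert not any("σ" in s for s in sids)
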