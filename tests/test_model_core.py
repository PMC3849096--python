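"""Model data structures, SBML round trips, S assembly and statistics."""

import numpy as np
import pytest

from cofactorscope import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    build_stoich_matrix,
    classify_reactions,
    make_toy_model,
    model_statistics,
    models_equal,
    parse_gpr,
    read_sbml,
    write_sbml,
)


class TestGPRParsing:
    @pytest.mark.parametrize(
        "text,genes,rendered",
        [
            ("gA", {"gA"}, "gA"),
            ("gA and gB", {"gA", "gB"}, "gA and gB"),
            ("gA or gB", {"gA", "gB"}, "gA or gB"),
            ("(gA or gB) and gC", {"gA", "gB", "gC"}, "(gA or gB) and gC"),
            ("gA AND (gB OR gC)", {"gA", "gB", "gC"}, "gA and (gB or gC)"),
            ("", set(), ""),
        ],
    )
    def test_parse_and_render(self, text, genes, rendered):
        gpr = parse_gpr(text)
        assert gpr.genes() == genes
        assert gpr.to_string() == rendered

    def test_precedence_or_binds_weaker(self):
        gpr = parse_gpr("gA and gB or gC")
        assert gpr.op == "or"
        assert gpr.evaluate({"gA": False, "gB": True, "gC": True})
        assert not gpr.evaluate({"gA": False, "gB": True, "gC": False})

    @pytest.mark.parametrize("bad", ["gA and", "(gA or gB", "and gA", "gA gB and"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_gpr(bad)

    def test_evaluation_and_or_semantics(self):
        gpr = parse_gpr("gThA and gThB")
        assert not gpr.evaluate({"gThA": False, "gThB": True})
        iso = parse_gpr("g1 or g1b")
        assert iso.evaluate({"g1": False, "g1b": True})


class TestValidation:
    def test_bound_order_enforced(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="bad", stoichiometry={"m": -1.0}, lower_bound=1.0, upper_bound=-1.0)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="empty", stoichiometry={})

    def test_duplicate_ids_listed(self, toy1):
        toy1.reactions.append(toy1.reactions[0])
        with pytest.raises(ModelValidationError, match="duplicate"):
            toy1.validate()

    def test_unknown_metabolite_rejected(self, toy1):
        toy1.reactions[0].stoichiometry["ghost_c"] = 1.0
        with pytest.raises(ModelValidationError, match="ghost_c"):
            toy1.validate()

    def test_missing_objective_rejected(self, toy1):
        toy1.objective_id = ""
        with pytest.raises(ModelValidationError, match="objective"):
            toy1.validate()


class TestSBMLRoundTrip:
    @pytest.mark.parametrize("name", ["TOY1", "TOY1-dup", "TOY1-H"])
    def test_write_read_identity(self, name, tmp_path):
        model = make_toy_model(name)
        path = tmp_path / f"{name}.xml"
        write_sbml(model, str(path))
        again = read_sbml(str(path))
        assert models_equal(model, again, tol=1e-12)
        # and a second cycle through the emitted file is still the identity
        path2 = tmp_path / "again.xml"
        write_sbml(again, str(path2))
        assert models_equal(model, read_sbml(str(path2)), tol=1e-12)

    def test_reversible_bounds_preserved_exactly(self, tmp_path):
        model = make_toy_model("TOY1")
        model.reaction("RESP").lower_bound = -100.0
        path = tmp_path / "rev.xml"
        write_sbml(model, str(path))
        resp = read_sbml(str(path)).reaction("RESP")
        assert (resp.lower_bound, resp.upper_bound) == (-100.0, 100.0)

    def test_empty_gpr_omitted_from_file(self, toy1, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy1, str(path))
        text = path.read_text()
        # BIOMASS has no gene association; the reaction element must not
        # carry one while T_S (gene gT) must
        biomass_block = text.split('id="BIOMASS"')[1].split("</reaction>")[0]
        ts_block = text.split('id="T_S"')[1].split("</reaction>")[0]
        assert "geneProductAssociation" not in biomass_block
        assert "geneProductAssociation" in ts_block

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        from cofactorscope import SBMLParseError

        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model><unclosed></model></sbml>")
        with pytest.raises(SBMLParseError):
            read_sbml(str(bad))

    def test_inconsistent_bounds_in_file_rejected(self, toy1, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy1, str(path))
        text = path.read_text().replace(
            'value="-4"', 'value="200"'
        )  # EX_S lower bound becomes 200 > upper 100
        bad = tmp_path / "bad_bounds.xml"
        bad.write_text(text)
        with pytest.raises(ModelValidationError):
            read_sbml(str(bad))

    def _without_objective(self, model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(model, str(path))
        text = path.read_text()
        start = text.index("<fbc:listOfObjectives")
        end = text.index("</fbc:listOfObjectives>") + len("</fbc:listOfObjectives>")
        stripped = tmp_path / "noobj.xml"
        stripped.write_text(text[:start] + text[end:])
        return stripped

    def test_biomass_name_fallback_when_no_fbc_objective(self, tmp_path):
        model = make_toy_model("TOY1")
        model.reaction("DM_BIO").name = "demand closure"  # keep one biomass-like name
        stripped = self._without_objective(model, tmp_path)
        assert read_sbml(str(stripped)).objective_id == "BIOMASS"

    def test_ambiguous_biomass_fallback_is_an_error(self, tmp_path):
        model = make_toy_model("TOY1")  # both "biomass equation" and "biomass demand"
        stripped = self._without_objective(model, tmp_path)
        with pytest.raises(ModelValidationError, match="multiple biomass-like"):
            read_sbml(str(stripped))


class TestStoichMatrix:
    def test_toy1_dimensions_and_columns(self, toy1):
        sm = build_stoich_matrix(toy1)
        assert sm.coefficients.shape == (8, 8)
        col = sm.coefficients[:, sm.col_index["R_CAT"]]
        expected = {"S_c": -1.0, "NAD_c": -3.0, "PRE_c": 2.0, "NADH_c": 3.0}
        for met, coef in expected.items():
            assert col[sm.row_index[met]] == coef
        assert np.count_nonzero(col) == len(expected)

    def test_every_column_reproduces_its_reaction(self, toy1_dup):
        sm = build_stoich_matrix(toy1_dup)
        for rxn in toy1_dup.reactions:
            col = sm.coefficients[:, sm.col_index[rxn.id]]
            rebuilt = {
                mid: col[i] for mid, i in sm.row_index.items() if col[i] != 0.0
            }
            assert rebuilt == rxn.stoichiometry

    def test_empty_model_gives_0x0(self):
        model = MetabolicModel(
            id="empty", metabolites=[], reactions=[], objective_id=""
        )
        sm = build_stoich_matrix(model)
        assert sm.coefficients.shape == (0, 0)

    def test_single_exchange_column(self):
        model = MetabolicModel(
            id="one",
            metabolites=[Metabolite(id="A_e", compartment="e")],
            reactions=[
                Reaction(
                    id="EX_A",
                    stoichiometry={"A_e": -1.0},
                    lower_bound=-100.0,
                    category="exchange",
                )
            ],
            objective_id="EX_A",
        )
        sm = build_stoich_matrix(model)
        assert sm.coefficients.shape == (1, 1)
        assert sm.coefficients[0, 0] == -1.0


class TestClassification:
    def test_toy1_categories(self, toy1):
        cats = classify_reactions(toy1)
        assert cats["T_S"] == "transport"
        assert cats["EX_S"] == "exchange"
        assert cats["THD"] == "enzymatic"
        assert cats["DM_BIO"] == "demand"

    def test_proton_coupled_transhydrogenase_spans_compartments(self, toy1_h):
        # with periplasmic protons the reaction moves species across
        # membranes and classifies as transport
        assert classify_reactions(toy1_h)["THD"] == "transport"


class TestModelStatistics:
    def test_toy1_partition(self, toy1):
        stats = model_statistics(toy1)
        assert stats.reactions == 8
        assert stats.exchange == 1
        assert stats.transport == 1
        assert stats.demand == 1
        assert stats.reversible + stats.irreversible == stats.reactions
        assert stats.genes == 6

    def test_single_irreversible_reaction(self):
        model = MetabolicModel(
            id="m",
            metabolites=[Metabolite(id="A_c"), Metabolite(id="B_c")],
            reactions=[Reaction(id="R", stoichiometry={"A_c": -1.0, "B_c": 1.0})],
            objective_id="R",
        )
        stats = model_statistics(model)
        assert (stats.reversible, stats.irreversible) == (0, 1)

    @pytest.mark.parametrize("name", ["TOY1", "TOY1-dup", "TOY1-H"])
    def test_partitions_exhaustive_and_disjoint(self, name):
        model = make_toy_model(name)
        stats = model_statistics(model)
        assert stats.reversible + stats.irreversible == stats.reactions
        cats = classify_reactions(model)
        assert len(cats) == stats.reactions
        by_cat = {c: sum(1 for v in cats.values() if v == c) for c in set(cats.values())}
        assert sum(by_cat.values()) == stats.reactions
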