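"""Dead-end classification, balance auditing and redundancy detection."""

import pytest

from fluxkit import MetabolicModel, Metabolite, Reaction
from fluxkit.curation import (
    check_balance,
    find_deadends,
    find_redundant,
)


def simple_model(rxns, mets=None):
    if mets is None:
        ids = sorted({m for r in rxns for m in r.stoichiometry})
        mets = [
            Metabolite(i, compartment=i[i.find("[") + 1 : -1] if "[" in i else "c")
            for i in ids
        ]
    return MetabolicModel(metabolites=mets, reactions=rxns)


class TestDeadends:
    def test_planted_deadends_recovered_exactly(self, random_model_factory):
        for seed in (0, 1, 2):
            model, ledger = random_model_factory(seed=seed)
            report = find_deadends(model)
            assert report.deadends == ledger["deadends"]

    def test_produced_and_consumed_by_irreversible_pair_is_ok(self):
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "b[c]": 1.0}),
            Reaction("r2", {"b[c]": -1.0, "c[c]": 1.0}),
        ])
        assert find_deadends(m).labels["b[c]"] == "ok"

    def test_reversible_participation_never_deadend(self):
        """Reversibility makes a metabolite both producible and consumable."""
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "b[c]": 1.0}, lower_bound=-1000.0),
        ])
        report = find_deadends(m)
        assert report.labels["a[c]"] == "oneSub_Product"
        assert report.labels["b[c]"] == "oneSub_Product"
        assert report.deadends == []

    def test_many_reversible_reactions_flagged_manysub(self):
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "b[c]": 1.0}, lower_bound=-1000.0),
            Reaction("r2", {"a[c]": -1.0, "c[c]": 1.0}, lower_bound=-1000.0),
        ])
        assert find_deadends(m).labels["a[c]"] == "ManySub_Product"

    def test_multi_compartment_deadend_suggests_transport(self):
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "x[c]": 1.0}),
            Reaction("r2", {"a[m]": -1.0, "x[m]": 1.0}),
            Reaction("r3", {"x[c]": -1.0, "a[c]": 1.0}),
            Reaction("r4", {"x[m]": -1.0, "a[m]": 1.0}),
            Reaction("r5", {"a[c]": -1.0, "dead[c]": 1.0}),
        ] + [Reaction("r6", {"dead[m]": -1.0, "a[m]": 1.0})])
        report = find_deadends(m)
        # dead[c] only produced, dead[m] only consumed; both exist in 2
        # compartments, so transport is the suggested explanation
        assert report.labels["dead[c]"] == "may_need_transport"
        assert report.labels["dead[m]"] == "may_need_transport"
        assert set(report.deadends) == {"dead[c]", "dead[m]"}

    def test_exchange_exclusion_default_and_override(self):
        mets = [Metabolite("a[e]", compartment="e"),
                Metabolite("a[c]", compartment="c")]
        rxns = [
            Reaction("EX_a", {"a[e]": -1.0}, -1000.0, 1000.0, category="exchange"),
            Reaction("T_a", {"a[e]": -1.0, "a[c]": 1.0}),
        ]
        m = MetabolicModel(metabolites=mets, reactions=rxns)
        # with exchanges excluded the boundary species a[e] is not a gap,
        # but a[c] (only produced) is
        rep = find_deadends(m, exclude_exchange=True)
        assert rep.labels["a[e]"] == "ok"
        assert rep.labels["a[c]"] in ("is_deadend", "may_need_transport")
        # including exchanges, a[e] becomes producible/consumable via EX
        rep2 = find_deadends(m, exclude_exchange=False)
        assert "a[e]" not in rep2.deadends

    def test_invariant_under_reaction_reorder_and_scaling(self, random_model_factory):
        model, _ = random_model_factory(seed=13)
        base = find_deadends(model)
        shuffled = model.copy()
        shuffled.reactions = list(reversed(shuffled.reactions))
        for r in shuffled.reactions:
            r.stoichiometry = {k: 3.0 * v for k, v in r.stoichiometry.items()}
        assert find_deadends(shuffled).labels == base.labels

    def test_deadend_reactions_listed(self, random_model_factory):
        model, ledger = random_model_factory(seed=4)
        report = find_deadends(model)
        for rid in report.deadend_reactions:
            r = model.get_reaction(rid)
            assert any(mid in report.deadends for mid in r.metabolite_ids())


def _met(mid, formula, charge=0):
    comp = mid[mid.find("[") + 1 : -1]
    from fluxkit.model import parse_formula

    return Metabolite(mid, compartment=comp, formula=parse_formula(formula),
                      charge=charge)


class TestBalance:
    def test_identity_reaction_balanced(self):
        m = MetabolicModel(
            metabolites=[_met("a[c]", "C2H6O"), _met("b[c]", "C2H6O")],
            reactions=[Reaction("r", {"a[c]": -1.0, "b[c]": 1.0})],
        )
        entry = check_balance(m.reactions[0], m)
        assert entry.balanced and entry.element_deficit == {}

    def test_missing_product_proton_detected_and_fix_suggested(self):
        """Hexokinase written without the product proton: deficit H -1,
        charge -1, the classic dropped-H+ database error."""
        m = MetabolicModel(
            metabolites=[
                _met("glc[c]", "C6H12O6", 0),
                _met("atp[c]", "C10H12N5O13P3", -4),
                _met("g6p[c]", "C6H11O9P", -2),
                _met("adp[c]", "C10H12N5O10P2", -3),
            ],
            reactions=[
                Reaction("HEX", {"glc[c]": -1.0, "atp[c]": -1.0,
                                 "g6p[c]": 1.0, "adp[c]": 1.0})
            ],
        )
        entry = check_balance(m.reactions[0], m)
        assert entry.status == "unbalanced"
        assert entry.element_deficit == {"H": -1}
        assert entry.charge_deficit == pytest.approx(-1)
        assert "proton" in entry.suggested_fix

    def test_exchange_and_biomass_skipped(self, core):
        ex = core.model.get_reaction("EX_glc")
        bio = core.model.get_reaction("BIOMASS")
        assert check_balance(ex, core.model).status == "skipped"
        assert check_balance(bio, core.model).status == "skipped"

    def test_missing_formula_is_unauditable_not_failure(self):
        m = MetabolicModel(
            metabolites=[Metabolite("a[c]", compartment="c"),
                         _met("b[c]", "CH4")],
            reactions=[Reaction("r", {"a[c]": -1.0, "b[c]": 1.0})],
        )
        assert check_balance(m.reactions[0], m).status == "unauditable"

    def test_reverse_reaction_negates_deficits(self):
        m = MetabolicModel(
            metabolites=[_met("a[c]", "C2H5"), _met("b[c]", "C2H4")],
            reactions=[
                Reaction("fwd", {"a[c]": -1.0, "b[c]": 1.0}),
                Reaction("rev", {"a[c]": 1.0, "b[c]": -1.0}),
            ],
        )
        d1 = check_balance(m.reactions[0], m).element_deficit
        d2 = check_balance(m.reactions[1], m).element_deficit
        assert d1 == {"H": -1} and d2 == {"H": 1}

    def test_opaque_moiety_tokens_conserved(self):
        m = MetabolicModel(
            metabolites=[_met("acp[c]", "R"), _met("malacp[c]", "C3H3O3R")],
            reactions=[Reaction("r", {"acp[c]": -1.0, "malacp[c]": 1.0})],
        )
        entry = check_balance(m.reactions[0], m)
        assert entry.status == "unbalanced"
        assert "R" not in entry.element_deficit  # the R moiety itself balances


class TestRedundancy:
    def test_two_copies_form_one_group(self):
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "b[c]": 1.0}),
            Reaction("r2", {"a[c]": -1.0, "b[c]": 1.0}),
            Reaction("r3", {"b[c]": -1.0, "a[c]": 2.0}),
        ])
        rep = find_redundant(m)
        assert rep.duplicate_groups == [["r1", "r2"]]

    def test_scalar_multiple_and_flip_count_as_duplicates(self):
        m = simple_model([
            Reaction("r1", {"a[c]": -1.0, "b[c]": 2.0}),
            Reaction("r2", {"a[c]": -0.5, "b[c]": 1.0}),
            Reaction("r3", {"a[c]": 1.0, "b[c]": -2.0}),
        ])
        assert find_redundant(m).duplicate_groups == [["r1", "r2", "r3"]]

    def test_isolated_reaction_detected(self):
        m = simple_model([
            Reaction("main", {"a[c]": -1.0, "b[c]": 1.0}),
            Reaction("island", {"x[c]": -1.0, "y[c]": 1.0}),
            Reaction("main2", {"b[c]": -1.0, "a[c]": 1.0}),
        ])
        assert find_redundant(m).isolated == ["island"]

    def test_planted_artifacts_recovered(self, random_model_factory):
        for seed in (3, 14):
            model, ledger = random_model_factory(seed=seed)
            rep = find_redundant(model)
            assert rep.duplicate_groups == ledger["duplicate_groups"]
            assert rep.isolated == ledger["isolated"]
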