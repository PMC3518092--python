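"""Minimal-medium search and substrate screening."""

import itertools

import pytest

from fluxkit import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    compare_predictions,
    determine_minimal_media,
    screen_substrates,
    solve_fba,
)
from fluxkit.media import SubstrateCall, SubstrateScreenResult


def five_nutrient_model():
    """Biomass needs nutrients A and B; C, D, E are dispensable.

    Five candidate exchanges; the unique minimal medium is {EX_A, EX_B}.
    """
    mets = []
    rxns = []
    for x in "ABCDE":
        mets += [Metabolite(f"{x.lower()}[e]", compartment="e"),
                 Metabolite(f"{x.lower()}[c]", compartment="c")]
        rxns.append(Reaction(f"EX_{x}", {f"{x.lower()}[e]": -1.0},
                             0.0, 1000.0, category="exchange"))
        rxns.append(Reaction(f"T_{x}", {f"{x.lower()}[e]": -1.0,
                                        f"{x.lower()}[c]": 1.0},
                             0.0, 1000.0, category="transport"))
    rxns.append(Reaction("BIO", {"a[c]": -1.0, "b[c]": -1.0},
                         0.0, 1000.0, category="biomass"))
    # sinks so the dispensable nutrients can at least flow
    for x in "CDE":
        rxns.append(Reaction(f"SINK_{x}", {f"{x.lower()}[c]": -1.0}, 0.0, 1000.0))
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          biomass_reaction_id="BIO")


def exhaustive_minimal_sets(model, candidates, carbon, threshold=1e-6):
    """All inclusion-minimal nutrient subsets supporting growth (2^n scan)."""
    feasible = []
    others = [c for c in candidates if c != carbon]
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            medium = {carbon: (-20.0, 1000.0)}
            medium.update({c: (-1000.0, 1000.0) for c in combo})
            res = solve_fba(apply_medium(model, medium))
            if res.optimal and res.objective_value > threshold:
                feasible.append(frozenset({carbon, *combo}))
    return [
        s for s in feasible
        if not any(t < s for t in feasible)
    ]


class TestMinimalMedia:
    def test_greedy_equals_exhaustive_on_five_candidates(self):
        model = five_nutrient_model()
        candidates = [f"EX_{x}" for x in "ABCDE"]
        medium = determine_minimal_media(model, "EX_A", candidates)
        minimal_sets = exhaustive_minimal_sets(model, candidates, "EX_A")
        assert len(minimal_sets) == 1
        assert set(medium) == set(minimal_sets[0]) == {"EX_A", "EX_B"}

    def test_result_supports_growth_and_is_locally_minimal(self, core):
        model = core.model
        medium = determine_minimal_media(model, "EX_glc", ["EX_glc", "EX_co2"],
                                         carbon_lb=-10.0)
        res = solve_fba(apply_medium(model, medium))
        assert res.objective_value > 1e-6
        for rid in medium:
            closed = dict(medium)
            closed[rid] = (0.0, 1000.0)
            z = solve_fba(apply_medium(model, closed)).objective_value or 0.0
            assert z <= 1e-6, f"closing {rid} should abolish growth"

    def test_carbon_lb_fixed_in_result(self):
        model = five_nutrient_model()
        medium = determine_minimal_media(
            model, "EX_A", [f"EX_{x}" for x in "ABCDE"], carbon_lb=-20.0
        )
        assert medium["EX_A"][0] == -20.0

    def test_error_when_pool_cannot_grow(self):
        model = five_nutrient_model()
        with pytest.raises(ValueError, match="cannot grow"):
            determine_minimal_media(model, "EX_C", ["EX_C", "EX_D"])

    def test_carbon_must_be_candidate(self):
        with pytest.raises(ValueError):
            determine_minimal_media(five_nutrient_model(), "EX_A", ["EX_B"])


def glycerol_toy():
    """Core-like toy with a glycerol assimilation branch (hand-checkable)."""
    from fluxkit.synth import SyntheticSpec, make_core_network

    model = make_core_network(SyntheticSpec()).model.copy()
    model.metabolites += [
        Metabolite("glyc[e]", "glycerol", "e", {"C": 3}, 0),
        Metabolite("glyc[c]", "glycerol", "c", {"C": 3}, 0),
    ]
    model.reactions += [
        Reaction("T_glyc", {"glyc[e]": -1.0, "glyc[c]": 1.0}, 0.0, 1000.0,
                 category="transport"),
        Reaction("R_glyk", {"glyc[c]": -1.0, "adp[c]": -1.0, "pi[c]": -1.0,
                            "pyr[c]": 1.0, "atp[c]": 1.0}, 0.0, 1000.0),
    ]
    return model


class TestScreening:
    def test_assimilable_substrate_predicted_positive(self):
        model = glycerol_toy()
        base = {"EX_co2": (-1000.0, 1000.0)}  # no carbon source
        res = screen_substrates(model, base, ["glyc[e]", "glc[e]"])
        assert res.call_for("glyc[e]").predicted
        assert res.call_for("glc[e]").predicted

    def test_substrate_without_pathway_negative(self, core):
        base = {"EX_co2": (-1000.0, 1000.0)}
        res = screen_substrates(core.model, base, ["unknown[e]"])
        call = res.call_for("unknown[e]")
        assert not call.predicted and call.reason == "no pathway"

    def test_order_independence(self, core):
        base = {"EX_co2": (-1000.0, 1000.0)}
        subs = ["glc[e]", "co2[e]", "unknown[e]"]
        a = screen_substrates(core.model, base, subs)
        b = screen_substrates(core.model, base, list(reversed(subs)))
        for s in subs:
            assert a.call_for(s).predicted == b.call_for(s).predicted
            assert a.call_for(s).growth == pytest.approx(b.call_for(s).growth)

    def test_adding_exchange_never_decreases_growth(self, core):
        base = {"EX_co2": (-1000.0, 1000.0), "EX_glc": (-10.0, 1000.0)}
        z0 = solve_fba(apply_medium(core.model, base)).objective_value
        res = screen_substrates(core.model, dict(base), ["co2[e]"])
        assert res.call_for("co2[e]").growth >= z0 - 1e-9


class TestComparison:
    def test_perfect_agreement(self):
        res = SubstrateScreenResult(calls=[
            SubstrateCall("s1", 1.0, True, True),
            SubstrateCall("s2", 0.0, False, False),
        ])
        cmp_ = compare_predictions(res)
        assert cmp_.accuracy == 1.0 and cmp_.gn == [] and cmp_.ng == []

    def test_gn_ng_classification(self):
        res = SubstrateScreenResult(calls=[
            SubstrateCall("grows_only_in_vivo", 0.0, False, True),
            SubstrateCall("grows_only_in_silico", 1.0, True, False),
            SubstrateCall("both", 1.0, True, True),
        ])
        cmp_ = compare_predictions(res)
        assert cmp_.gn == ["grows_only_in_vivo"]
        assert cmp_.ng == ["grows_only_in_silico"]
        assert cmp_.accuracy == pytest.approx(1 / 3)

    def test_recount_matches_brute_force(self):
        import numpy as np

        rng = np.random.default_rng(0)
        calls = [
            SubstrateCall(f"s{i}", 0.0, bool(rng.integers(2)), bool(rng.integers(2)))
            for i in range(40)
        ]
        cmp_ = compare_predictions(SubstrateScreenResult(calls=calls))
        manual = sum(c.predicted == c.observed for c in calls) / 40
        assert cmp_.accuracy == pytest.approx(manual)

    def test_requires_observations(self):
        with pytest.raises(ValueError):
            compare_predictions(
                SubstrateScreenResult(calls=[SubstrateCall("s", 0.0, False)])
            )
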