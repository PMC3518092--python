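"""FBA correctness against the brute-force vertex oracle, LP invariants,
and maintenance-energy estimation."""

import numpy as np
import pytest

from fluxkit import (
    MaintenanceParams,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_maintenance,
    estimate_maintenance,
    make_chemostat_data,
    solve_fba,
)
from fluxkit.model import build_stoichiometric_matrix
from fluxkit.synth import SyntheticSpec, make_core_network
from fluxkit.validation import brute_force_fba


def chain_with_uptake(u):
    """Aex -> A -> B -> drain with unit yields: optimum equals uptake u."""
    mets = [Metabolite("a[e]", compartment="e"),
            Metabolite("a[c]", compartment="c"),
            Metabolite("b[c]", compartment="c")]
    rxns = [
        Reaction("EX_a", {"a[e]": -1.0}, -u, 1000.0, category="exchange"),
        Reaction("T_a", {"a[e]": -1.0, "a[c]": 1.0}, 0.0, 1000.0),
        Reaction("CONV", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 1000.0),
        Reaction("BIO", {"b[c]": -1.0}, 0.0, 1000.0, category="biomass"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          biomass_reaction_id="BIO")


class TestSolveFba:
    def test_linear_chain_optimum_equals_uptake_bound(self):
        for u in (0.0, 3.5, 20.0):
            res = solve_fba(chain_with_uptake(u))
            assert res.optimal
            assert res.objective_value == pytest.approx(u, abs=1e-9)

    def test_core_network_matches_closed_form(self, core):
        res = solve_fba(core.model)
        assert res.objective_value == pytest.approx(core.optimum, rel=1e-9)

    def test_all_exchanges_closed_gives_zero_growth(self, core):
        m = core.model.copy()
        m.get_reaction("ATPM").lower_bound = 0.0
        m.get_reaction("ATPM").upper_bound = 0.0
        for r in m.reactions:
            if r.category == "exchange":
                r.lower_bound = 0.0
        res = solve_fba(m)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_matches_vertex_oracle_on_random_networks(self, tiny_model_factory):
        both_optimal = 0
        for seed in range(120):
            model = tiny_model_factory(seed)
            res = solve_fba(model)
            z_oracle, _ = brute_force_fba(model)
            if z_oracle is None:
                assert res.status == "infeasible"
            else:
                assert res.optimal
                assert res.objective_value == pytest.approx(z_oracle, abs=1e-8)
                both_optimal += 1
        assert both_optimal >= 60  # the comparison must actually exercise LPs

    def test_steady_state_residual_small(self, core):
        res = solve_fba(core.model)
        S, _, rxn_ids = build_stoichiometric_matrix(core.model)
        v = np.array([res.fluxes[r] for r in rxn_ids])
        assert np.abs(S @ v).max() <= 1e-6

    def test_bounds_respected(self, core):
        res = solve_fba(core.model)
        for r in core.model.reactions:
            assert r.lower_bound - 1e-9 <= res.fluxes[r.id] <= r.upper_bound + 1e-9

    def test_monotone_in_relaxed_bound(self):
        z = [solve_fba(chain_with_uptake(u)).objective_value
             for u in (1.0, 2.0, 5.0)]
        assert z == sorted(z)

    def test_homogeneity_under_bound_scaling(self, tiny_model_factory):
        lam = 3.0
        for seed in (2, 6, 10):
            model = tiny_model_factory(seed)
            res = solve_fba(model)
            scaled = model.copy()
            for r in scaled.reactions:
                r.lower_bound *= lam
                r.upper_bound *= lam
            res2 = solve_fba(scaled)
            if res.optimal:
                assert res2.objective_value == pytest.approx(
                    lam * res.objective_value, abs=1e-7
                )

    def test_infeasible_and_missing_objective_reported(self):
        m = chain_with_uptake(1.0)
        m.get_reaction("CONV").lower_bound = 5.0  # forces more than uptake
        m.get_reaction("CONV").upper_bound = 5.0
        res = solve_fba(m)
        assert res.status == "infeasible" and res.fluxes == {}
        with pytest.raises(KeyError):
            solve_fba(chain_with_uptake(1.0), objective="NOPE")


class TestMaintenance:
    def test_apply_pins_atpm_bounds(self, core):
        out = apply_maintenance(core.model, MaintenanceParams(ngam=7.8625, gam=0.0))
        atpm = out.get_reaction("ATPM")
        assert (atpm.lower_bound, atpm.upper_bound) == (7.8625, 7.8625)

    def test_zero_params_leave_model_inert(self, core):
        out = apply_maintenance(core.model, MaintenanceParams(ngam=0.0, gam=0.0))
        atpm = out.get_reaction("ATPM")
        assert (atpm.lower_bound, atpm.upper_bound) == (0.0, 0.0)

    def test_raising_ngam_weakly_decreases_growth(self, core):
        zs = []
        for ngam in (0.0, 2.0, 8.0, 20.0):
            out = apply_maintenance(core.model, MaintenanceParams(ngam=ngam, gam=0.0))
            zs.append(solve_fba(out).objective_value)
        assert all(a >= b - 1e-9 for a, b in zip(zs, zs[1:]))

    def test_creates_reaction_when_absent(self):
        m = chain_with_uptake(1.0)
        m.metabolites += [Metabolite("atp[c]", compartment="c"),
                          Metabolite("adp[c]", compartment="c")]
        out = apply_maintenance(
            m, MaintenanceParams(ngam=1.5, gam=0.0),
            energy_ids={"atp": "atp[c]", "adp": "adp[c]"},
        )
        atpm = out.get_reaction("ATPM")
        assert atpm.stoichiometry == {"atp[c]": -1.0, "adp[c]": 1.0}
        assert atpm.lower_bound == 1.5


class TestEstimateMaintenance:
    def test_two_noise_free_points_recover_exactly(self):
        gam, ngam, y = 86.7881, 7.8625, 18.5
        pts = [(d, (ngam + gam * d) / y) for d in (0.05, 0.2)]
        p = estimate_maintenance(pts, atp_yield=y)
        assert p.gam == pytest.approx(gam, rel=1e-12)
        assert p.ngam == pytest.approx(ngam, rel=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        df = make_chemostat_data(sigma=0.02, seed=7)
        p = estimate_maintenance(list(zip(df.dilution_rate, df.uptake)))
        assert abs(p.gam - 86.7881) / 86.7881 < 0.05
        assert abs(p.ngam - 7.8625) / 7.8625 < 0.05

    def test_default_atp_yield(self):
        assert MaintenanceParams(ngam=0, gam=0).atp_yield == 18.5

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            estimate_maintenance([(0.1, 5.0)])
        with pytest.raises(ValueError):
            estimate_maintenance([(0.1, 5.0), (0.1, 6.0)])


class TestCoreTemplate:
    def test_infeasible_when_ngam_exceeds_supply(self):
        cn = make_core_network(SyntheticSpec(uptake=1.0, ngam=100.0))
        assert not cn.feasible
        res = solve_fba(cn.model)
        assert res.status == "infeasible"

    def test_zero_uptake_zero_growth(self):
        cn = make_core_network(SyntheticSpec(uptake=0.0, ngam=0.0))
        assert cn.optimum == pytest.approx(0.0)
        assert solve_fba(cn.model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_matches_lp_across_parameters(self):
        for u, gam, ngam, bp in [(10, 2, 0.5, 1.0), (5, 9, 1.0, 1.0),
                                 (10, 1.2, 0.0, 1.0), (3, 4, 2.0, 0.5)]:
            cn = make_core_network(
                SyntheticSpec(uptake=u, gam=gam, ngam=ngam, biomass_pyruvate=bp)
            )
            res = solve_fba(cn.model)
            assert res.objective_value == pytest.approx(cn.optimum, rel=1e-9, abs=1e-9)
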