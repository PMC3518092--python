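"""Shared fixtures: synthetic networks and tiny random flux polytopes."""

from __future__ import annotations

import numpy as np
import pytest

from fluxkit import MetabolicModel, Metabolite, Reaction, SyntheticSpec
from fluxkit.synth import make_core_network, make_random_network


@pytest.fixture(scope="session")
def core():
    """Default core template with its closed-form optimum."""
    return make_core_network(SyntheticSpec())


@pytest.fixture()
def random_model_factory():
    def build(seed: int, **kwargs):
        defaults = dict(
            n_extra_metabolites=2, planted_deadends=3, planted_duplicates=2,
            planted_isolated=1, planted_essential=1,
        )
        defaults.update(kwargs)
        return make_random_network(SyntheticSpec(seed=seed, **defaults))

    return build


def make_tiny_model(seed: int) -> MetabolicModel:
    """A random small flux polytope (≤8 reactions) for solver validation.

    Coefficients are small integers and all bounds finite, so brute-force
    vertex enumeration applies exactly; some instances are deliberately
    infeasible (a variable's bounds may exclude zero).
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(1, 5))
    n_rxns = int(rng.integers(2, 9))
    mets = [Metabolite(f"m{i}[c]", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            coef = int(rng.integers(-3, 4))
            if coef:
                stoich[f"m{i}[c]"] = float(coef)
        if not stoich:
            stoich[f"m{int(rng.integers(n_mets))}[c]"] = 1.0
        lb = float(rng.choice([-10.0, -5.0, 0.0, 1.0]))
        ub = float(rng.choice([0.0, 2.0, 5.0, 10.0]))
        if ub < lb:
            lb, ub = ub, lb
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    c = {f"r{j}": float(rng.integers(-2, 3)) for j in range(n_rxns)}
    if all(v == 0 for v in c.values()):
        c["r0"] = 1.0
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=[],
        objective_coefficients=c, id=f"tiny{seed}",
        compartments={"c": "cytoplasm"},
    )
    model.validate()
    return model


@pytest.fixture()
def tiny_model_factory():
    return make_tiny_model
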