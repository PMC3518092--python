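"""Synthetic metabolic networks with known ground truth.

The generator grows networks from a hand-derivable core template — a
glucose-like uptake, two parallel glycolysis-like routes of different ATP
yield, a respiration step, a fixed ATP-maintenance drain and a biomass
reaction with growth-associated ATP demand — so that every generated model
admits growth and its FBA optimum has a closed form.  Planted features
(dead-ends, duplicate and isolated reactions, essential genes, isozyme
pairs, a latent bypass branch) are recorded in a ground-truth ledger so
curation, essentiality and FVA analyses can be checked for exact recovery.

Core template closed form
-------------------------
With uptake bound u, maintenance NGAM, biomass demanding b_p pyruvate and
GAM ATP per unit, the efficient route yields 2 ATP + 2 pyruvate per
glucose and respiration 3 ATP per pyruvate, so the ATP-limited optimum is
(8u − NGAM)/(GAM + 3·b_p) and the pyruvate-limited optimum 2u/b_p; the
growth optimum is the smaller of the two, and the model is infeasible when
NGAM exceeds the maximal ATP production rate 8u.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)


@dataclass
class SyntheticSpec:
    """Parameters of a generated network; the seed fully determines it."""

    seed: int = 0
    uptake: float = 10.0
    gam: float = 2.0          # ATP per unit biomass (template units)
    ngam: float = 0.5         # fixed ATP maintenance flux
    biomass_pyruvate: float = 1.0  # pyruvate per unit biomass
    n_extra_metabolites: int = 0
    planted_deadends: int = 0
    planted_duplicates: int = 0
    planted_isolated: int = 0
    planted_essential: int = 0     # extra genes AND-ed into the uptake GPR
    resp_isozyme: bool = False     # give respiration an OR-redundant isozyme

    def validate(self) -> None:
        if self.uptake < 0 or self.ngam < 0:
            raise ValueError("uptake and ngam must be non-negative")
        if self.gam <= self.biomass_pyruvate:
            # keeps the respiration knockout's zero-growth ground truth exact
            raise ValueError(
                "inconsistent yields: gam must exceed the biomass pyruvate "
                "demand for the template's closed form to hold"
            )
        for k in ("n_extra_metabolites", "planted_deadends",
                  "planted_duplicates", "planted_isolated", "planted_essential"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")


def _core_optimum(u: float, ngam: float, gam: float, b_p: float) -> float | None:
    """Closed-form growth optimum of the template; None when infeasible."""
    if 8.0 * u < ngam:
        return None
    return min((8.0 * u - ngam) / (gam + 3.0 * b_p), 2.0 * u / b_p)


@dataclass
class CoreNetwork:
    model: MetabolicModel
    optimum: float | None  # None: infeasible under the stated maintenance
    ledger: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.optimum is not None


def make_core_network(spec: SyntheticSpec | None = None, **kwargs) -> CoreNetwork:
    """Build the core template and its analytically known optimum."""
    spec = spec or SyntheticSpec(**kwargs)
    spec.validate()
    u, ngam, gam, b_p = spec.uptake, spec.ngam, spec.gam, spec.biomass_pyruvate

    mets = [
        Metabolite("glc[e]", "glucose", "e", {"C": 6}, 0),
        Metabolite("glc[c]", "glucose", "c", {"C": 6}, 0),
        Metabolite("pyr[c]", "pyruvate", "c", {"C": 3}, 0),
        Metabolite("atp[c]", "ATP", "c", {"X": 3, "P": 3}, 0),
        Metabolite("adp[c]", "ADP", "c", {"X": 3, "P": 2}, 0),
        Metabolite("pi[c]", "phosphate", "c", {"P": 1}, 0),
        Metabolite("co2[c]", "CO2", "c", {"C": 1}, 0),
        Metabolite("co2[e]", "CO2", "e", {"C": 1}, 0),
    ]
    B = DEFAULT_BOUND
    rxns = [
        Reaction("EX_glc", {"glc[e]": -1.0}, -u, B, None, "exchange",
                 "glucose exchange"),
        Reaction("T_glc", {"glc[e]": -1.0, "glc[c]": 1.0}, 0.0, B, "gT",
                 "transport", "glucose uptake transporter"),
        Reaction("R_gly1", {"glc[c]": -1.0, "adp[c]": -2.0, "pi[c]": -2.0,
                            "pyr[c]": 2.0, "atp[c]": 2.0}, 0.0, B, "g1",
                 "metabolic", "glycolysis, efficient route"),
        Reaction("R_gly2", {"glc[c]": -1.0, "adp[c]": -1.0, "pi[c]": -1.0,
                            "pyr[c]": 2.0, "atp[c]": 1.0}, 0.0, B, "g2",
                 "metabolic", "glycolysis, bypass route"),
        Reaction("R_resp", {"pyr[c]": -1.0, "adp[c]": -3.0, "pi[c]": -3.0,
                            "atp[c]": 3.0, "co2[c]": 3.0}, 0.0, B,
                 "gR or gRiso" if spec.resp_isozyme else "gR",
                 "metabolic", "respiration"),
        Reaction("ATPM", {"atp[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0},
                 ngam, ngam, None, "metabolic", "ATP maintenance"),
        Reaction("T_co2", {"co2[c]": -1.0, "co2[e]": 1.0}, 0.0, B,
                 "gc1 or gc2", "transport", "CO2 export"),
        Reaction("EX_co2", {"co2[e]": -1.0}, -B, B, None, "exchange",
                 "CO2 exchange"),
        Reaction("BIOMASS", {"pyr[c]": -b_p, "atp[c]": -gam,
                             "adp[c]": gam, "pi[c]": gam}, 0.0, B, None,
                 "biomass", "biomass synthesis"),
    ]
    if spec.planted_essential:
        from .gpr import parse_gpr

        extra = [f"gE{i}" for i in range(spec.planted_essential)]
        rxns[1].gpr = parse_gpr(" and ".join(["gT"] + extra))

    genes = sorted({g for r in rxns for g in r.genes})
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes,
        biomass_reaction_id="BIOMASS",
        id=f"synthetic_core_seed{spec.seed}",
        compartments={"e": "extracellular", "c": "cytoplasm"},
    )
    model.validate()
    optimum = _core_optimum(u, ngam, gam, b_p)
    ledger = _core_ledger(spec, optimum)
    return CoreNetwork(model=model, optimum=optimum, ledger=ledger)


def _core_ledger(spec: SyntheticSpec, optimum: float | None) -> dict:
    u, ngam, gam, b_p = spec.uptake, spec.ngam, spec.gam, spec.biomass_pyruvate
    ledger: dict = {"optimum": optimum}
    if optimum is None or optimum <= 0:
        return ledger
    essential = ["gT"] + [f"gE{i}" for i in range(spec.planted_essential)]
    non_essential = ["gc1", "gc2"]
    partially = []
    if spec.resp_isozyme:
        non_essential += ["gR", "gRiso"]
    else:
        essential.append("gR")
    # bypass-only optimum after knocking out the efficient route
    z_g1 = max(min((7.0 * u - ngam) / (gam + 3.0 * b_p), 2.0 * u / b_p), 0.0)
    ratio = z_g1 / optimum
    if ratio < 1e-6:
        essential.append("g1")
    elif ratio > 1 - 1e-3:
        non_essential.append("g1")
    else:
        partially.append("g1")
    non_essential.append("g2")
    ledger.update(
        essential=sorted(essential),
        partially_essential=sorted(partially),
        non_essential=sorted(non_essential),
    )
    # latent bypass: R_gly2 is pinned to zero on the wild-type optimal face
    # (ATP-limited regime) and switches on when g1 is deleted and growth
    # stays positive
    atp_limited = (8.0 * u - ngam) / (gam + 3.0 * b_p) <= 2.0 * u / b_p
    if atp_limited and "g1" not in essential and z_g1 > 0:
        ledger["group1"] = [["R_gly2", "g1"]]
        ledger["group2"] = [["R_gly2", "g1"]]
        ledger["group_activation"] = u  # bypass carries the full uptake
    else:
        ledger["group1"] = []
        ledger["group2"] = []
    return ledger


def make_random_network(
    spec: SyntheticSpec,
) -> tuple[MetabolicModel, dict]:
    """Grow a randomized network from the core and return it with a ledger.

    The ledger records every planted artefact: dead-end metabolites
    (including the two created by each isolated reaction), duplicate
    groups, isolated reactions, per-gene essentiality labels, the
    oneSub_Product metabolites of the reversible appendix chains, the hub
    metabolite's connectivity, census counts and the closed-form optimum.
    The same seed always reproduces the identical model.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    core = make_core_network(spec)
    model, ledger = core.model, dict(core.ledger)
    model.id = f"synthetic_random_seed{spec.seed}"
    B = DEFAULT_BOUND

    deadends: list[str] = []
    onesub: list[str] = []
    isolated: list[str] = []
    dup_members: dict[str, list[str]] = {}
    hub = "pyr[c]"
    hub_count = sum(
        1 for r in model.reactions if r.stoichiometry.get(hub, 0.0) != 0
    )

    # reversible appendix chains pyr <=> rM_i <=> rN_i: connected, carry no
    # net flux, exercise the oneSub/ManySub classifier without new dead-ends
    for i in range(spec.n_extra_metabolites):
        a, b = f"xM{i}[c]", f"xN{i}[c]"
        model.metabolites.append(Metabolite(a, f"appendix {i}a", "c", {"C": 3}, 0))
        model.metabolites.append(Metabolite(b, f"appendix {i}b", "c", {"C": 3}, 0))
        model.reactions.append(
            Reaction(f"XA{i}", {hub: -1.0, a: 1.0}, -B, B, None, "metabolic")
        )
        model.reactions.append(
            Reaction(f"XB{i}", {a: -1.0, b: 1.0}, -B, B, None, "metabolic")
        )
        hub_count += 1
        onesub.append(b)  # b sits in exactly one reversible reaction

    for i in range(spec.planted_deadends):
        mid = f"dd{i}[c]"
        model.metabolites.append(Metabolite(mid, f"dead end {i}", "c", {"C": 3}, 0))
        model.reactions.append(
            Reaction(f"DDR{i}", {hub: -1.0, mid: 1.0}, 0.0, B, None, "metabolic")
        )
        hub_count += 1
        deadends.append(mid)

    for i in range(spec.planted_isolated):
        a, b = f"isoA{i}[c]", f"isoB{i}[c]"
        model.metabolites.append(Metabolite(a, f"isolated {i}a", "c", {"C": 1}, 0))
        model.metabolites.append(Metabolite(b, f"isolated {i}b", "c", {"C": 1}, 0))
        rid = f"ISO{i}"
        model.reactions.append(
            Reaction(rid, {a: -1.0, b: 1.0}, 0.0, B, None, "metabolic")
        )
        isolated.append(rid)
        deadends += [a, b]  # only-consumed and only-produced respectively

    # scaled copies (coefficients x2) of flux-safe core reactions; copying
    # the GPR keeps essentiality ground truth intact
    dup_targets = ["R_gly1", "R_resp"]
    for i in range(spec.planted_duplicates):
        target = dup_targets[int(rng.integers(len(dup_targets)))]
        src = model.get_reaction(target)
        rid = f"DUP{i}_{target}"
        model.reactions.append(
            Reaction(
                rid,
                {mid: 2.0 * coef for mid, coef in src.stoichiometry.items()},
                src.lower_bound, src.upper_bound,
                src.gpr.to_string() if src.gpr else None,
                src.category, f"duplicate of {target}",
            )
        )
        dup_members.setdefault(target, []).append(rid)
        if hub in src.stoichiometry:
            hub_count += 1

    model.genes = sorted({g for r in model.reactions for g in r.genes})
    model.validate()

    n_exchange = 2
    n_transport = 2 + sum(
        1 for t, ids in dup_members.items() if t == "T_glc" for _ in ids
    )
    ledger.update(
        deadends=sorted(deadends),
        onesub=sorted(onesub),
        isolated=sorted(isolated),
        duplicate_groups=sorted(
            sorted([t] + ids) for t, ids in dup_members.items()
        ),
        hub=hub,
        hub_connectivity=hub_count,
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_exchange=n_exchange,
        n_transport=n_transport,
    )
    return model, ledger


def make_chemostat_data(
    gam: float = 86.7881,
    ngam: float = 7.8625,
    atp_yield: float = 18.5,
    dilution_rates: Sequence[float] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate chemostat substrate-uptake measurements.

    At steady state the specific growth rate equals the dilution rate D,
    so the ATP demand is NGAM + GAM·D and the substrate uptake
    (NGAM + GAM·D)/atp_yield.  ``sigma`` is the relative standard
    deviation of multiplicative Gaussian measurement noise on the uptake
    rate.  Defaults reproduce the glycerol-chemostat setting (full
    oxidation of one glycerol yielding 18.5 ATP).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if dilution_rates is None:
        dilution_rates = np.linspace(0.02, 0.25, 20)
    D = np.asarray(dilution_rates, float)
    uptake = (ngam + gam * D) / atp_yield
    if sigma > 0:
        rng = np.random.default_rng(seed)
        uptake = uptake * (1.0 + rng.normal(0.0, sigma, size=D.shape))
    return pd.DataFrame({"dilution_rate": D, "uptake": uptake})


def write_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
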