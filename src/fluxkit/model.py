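"""Core data model for compartmentalized metabolic networks.

A :class:`MetabolicModel` holds metabolites (with compartment, formula and
charge), reactions (stoichiometry, flux bounds in mmol·gDCW⁻¹·h⁻¹, GPR
rule, category) and a designated biomass reaction.  The stoichiometric
matrix S (metabolites × reactions) is the central object of constraint-based
analysis: steady state requires S·v = 0 for the flux vector v.

Conventions
-----------
* Negative stoichiometric coefficients denote consumption.
* Exchange reactions are boundary pseudo-reactions touching exactly one
  extracellular metabolite; negative exchange flux denotes uptake.
* A reaction is reversible iff its lower bound is negative; default bounds
  are [-1000, 1000] (reversible) or [0, 1000] (irreversible).
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GprExpression, parse_gpr

DEFAULT_BOUND = 1000.0

#: Reaction categories recognised by the census.
CATEGORIES = ("metabolic", "transport", "exchange", "biomass", "spontaneous")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


def parse_formula(text: str | None) -> dict[str, int] | None:
    """Parse a chemical formula string into an element→count mapping.

    Element symbols are an uppercase letter followed by lowercase letters;
    non-standard symbols (R-groups, polymer units) are kept as opaque
    conserved tokens.  Returns None for empty input.
    """
    if text is None or not text.strip():
        return None
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def formula_to_string(formula: Mapping[str, int] | None) -> str:
    if not formula:
        return ""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items())
    )


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    @property
    def base_id(self) -> str:
        """Metabolite id with a trailing ``[compartment]`` tag stripped."""
        return re.sub(r"\[[^\]]*\]$", "", self.id)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR."""

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression | None = None
    category: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    def metabolite_ids(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c != 0]


@dataclass
class ModelCensus:
    """Counts of model constituents, broken down by category and compartment.

    ``n_reversible`` / ``n_irreversible`` partition the non-transport,
    non-exchange reactions (the convention under which reversible +
    irreversible equals the metabolic reaction count).
    """

    n_genes: int = 0
    n_reactions: int = 0
    n_metabolites: int = 0
    n_gene_associated: int = 0
    n_non_gene_associated: int = 0
    n_transport: int = 0
    n_exchange: int = 0
    n_metabolic: int = 0
    n_spontaneous: int = 0
    n_reversible: int = 0
    n_irreversible: int = 0
    metabolites_per_compartment: dict[str, int] = field(default_factory=dict)
    reactions_per_compartment: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int | dict[str, int]]:
        return {
            "genes": self.n_genes,
            "reactions": self.n_reactions,
            "metabolites": self.n_metabolites,
            "gene_associated": self.n_gene_associated,
            "non_gene_associated": self.n_non_gene_associated,
            "transport": self.n_transport,
            "exchange": self.n_exchange,
            "metabolic": self.n_metabolic,
            "spontaneous": self.n_spontaneous,
            "reversible": self.n_reversible,
            "irreversible": self.n_irreversible,
            "metabolites_per_compartment": dict(self.metabolites_per_compartment),
            "reactions_per_compartment": dict(self.reactions_per_compartment),
        }


@dataclass
class MetabolicModel:
    """A compartmentalized metabolic network."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    objective_coefficients: dict[str, float] = field(default_factory=dict)
    id: str = "model"
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = {
                "e": "extracellular",
                "c": "cytoplasm",
                "m": "mitochondrion",
            }
        if not self.objective_coefficients and self.biomass_reaction_id:
            self.objective_coefficients = {self.biomass_reaction_id: 1.0}

    # -- lookup ---------------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id}")

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id!r} has unknown compartment "
                    f"{m.compartment!r} (declared: {sorted(self.compartments)})"
                )
        seen_r: set[str] = set()
        met_comp = {m.id: m.compartment for m in self.metabolites}
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            missing = [mid for mid in r.stoichiometry if mid not in met_comp]
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {missing}"
                )
            if r.category == "exchange":
                mids = r.metabolite_ids()
                if len(mids) != 1 or met_comp[mids[0]] != "e":
                    raise ModelValidationError(
                        f"exchange reaction {r.id!r} must touch exactly one "
                        f"extracellular metabolite (touches {mids})"
                    )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in seen_r:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for rid in self.objective_coefficients:
            if rid not in seen_r:
                raise ModelValidationError(f"objective reaction {rid!r} not in model")
        declared = set(self.genes)
        for r in self.reactions:
            undeclared = r.genes - declared
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses undeclared genes {sorted(undeclared)}"
                )


def infer_category(reaction: Reaction, model: MetabolicModel) -> str:
    """Classify a reaction structurally when no category label is present.

    Exchange: a single extracellular metabolite.  Transport: spans ≥2
    compartments.  Biomass: the model's designated biomass reaction.
    Everything else is metabolic.
    """
    if reaction.category in CATEGORIES:
        return reaction.category
    if reaction.id == model.biomass_reaction_id:
        return "biomass"
    met_comp = {m.id: m.compartment for m in model.metabolites}
    comps = {met_comp[mid] for mid in reaction.metabolite_ids() if mid in met_comp}
    mids = reaction.metabolite_ids()
    if len(mids) == 1 and comps == {"e"}:
        return "exchange"
    if len(comps) >= 2:
        return "transport"
    return "metabolic"


def reaction_compartment(reaction: Reaction, model: MetabolicModel) -> str | None:
    """Assign a reaction to a single compartment.

    Single-compartment reactions belong to that compartment; reactions
    spanning several are assigned to the outermost compartment they touch
    (extracellular before cytoplasm before mitochondrion), so that the
    per-compartment reaction counts partition the reaction list.
    """
    met_comp = {m.id: m.compartment for m in model.metabolites}
    comps = {met_comp[mid] for mid in reaction.metabolite_ids() if mid in met_comp}
    if not comps:
        return None
    order = list(model.compartments)  # declaration order, outermost first
    for c in order:
        if c in comps:
            return c
    return sorted(comps)[0]


def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """S matrix with entry (i, j) = coefficient of metabolite i in reaction j.

    Row order follows the metabolite list, column order the reaction list.
    """
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    row_of = {mid: i for i, mid in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            if coef != 0:
                rows.append(row_of[mid])
                cols.append(j)
                data.append(float(coef))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return S, met_ids, rxn_ids


def connectivity(
    model: MetabolicModel, compartment: str | None = None
) -> dict[str, int]:
    """Number of reactions each metabolite participates in, sorted descending.

    With ``compartment`` given, only metabolite species of that compartment
    are reported (their counts still include every reaction touching that
    species, e.g. transport reactions crossing into the compartment).
    """
    if compartment is not None and compartment not in model.compartments:
        raise ValueError(
            f"unknown compartment {compartment!r}; declared: "
            f"{sorted(model.compartments)}"
        )
    counts: dict[str, int] = {
        m.id: 0
        for m in model.metabolites
        if compartment is None or m.compartment == compartment
    }
    for r in model.reactions:
        for mid, coef in r.stoichiometry.items():
            if coef != 0 and mid in counts:
                counts[mid] += 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def census(model: MetabolicModel) -> ModelCensus:
    """Tabulate model composition: categories, reversibility, compartments."""
    c = ModelCensus(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
    )
    for m in model.metabolites:
        c.metabolites_per_compartment[m.compartment] = (
            c.metabolites_per_compartment.get(m.compartment, 0) + 1
        )
    for r in model.reactions:
        cat = infer_category(r, model)
        if r.gpr is not None:
            c.n_gene_associated += 1
        else:
            c.n_non_gene_associated += 1
        if cat == "transport":
            c.n_transport += 1
        elif cat == "exchange":
            c.n_exchange += 1
        else:
            # biomass and spontaneous reactions count as metabolic here so
            # that reversible + irreversible = metabolic
            c.n_metabolic += 1
            if cat == "spontaneous":
                c.n_spontaneous += 1
            if r.reversible:
                c.n_reversible += 1
            else:
                c.n_irreversible += 1
        comp = reaction_compartment(r, model)
        if comp is not None:
            c.reactions_per_compartment[comp] = (
                c.reactions_per_compartment.get(comp, 0) + 1
            )
    return c


def build_biomass_reaction(
    model: MetabolicModel,
    composition: Mapping[str, float],
    gam: float = 0.0,
    reaction_id: str = "BIOMASS",
    energy_ids: Mapping[str, str] | None = None,
    biomass_metabolite_id: str | None = None,
) -> Reaction:
    """Assemble an irreversible biomass synthesis reaction.

    ``composition`` maps precursor metabolite ids to their demand in
    mmol·gDCW⁻¹ (consumed per unit biomass).  ``gam`` is the
    growth-associated maintenance in mmol ATP·gDCW⁻¹, added as ATP + H₂O →
    ADP + Pi + H hydrolysis scaled by ``gam``.  ``energy_ids`` maps the
    roles ``atp, adp, pi, h2o, h`` to metabolite ids; roles missing from the
    model are silently dropped (water/proton bookkeeping is optional in toy
    networks).  The reaction is a drain unless ``biomass_metabolite_id``
    names a species to produce.
    """
    known = {m.id for m in model.metabolites}
    unknown = [mid for mid in composition if mid not in known]
    if unknown:
        raise KeyError(f"biomass components not in model: {unknown}")
    for mid, coef in composition.items():
        if coef <= 0:
            raise ValueError(f"biomass component {mid!r} needs a positive coefficient")
    stoich = {mid: -float(coef) for mid, coef in composition.items()}
    if gam < 0:
        raise ValueError("gam must be non-negative")
    if gam > 0:
        roles = dict(energy_ids or {})
        signs = {"atp": -1.0, "h2o": -1.0, "adp": +1.0, "pi": +1.0, "h": +1.0}
        for role, sign in signs.items():
            mid = roles.get(role)
            if mid is None or mid not in known:
                continue
            stoich[mid] = stoich.get(mid, 0.0) + sign * gam
    if biomass_metabolite_id is not None:
        if biomass_metabolite_id not in known:
            raise KeyError(f"biomass metabolite {biomass_metabolite_id!r} not in model")
        stoich[biomass_metabolite_id] = stoich.get(biomass_metabolite_id, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        category="biomass",
        name="biomass synthesis",
    )


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Field-by-field structural equality of two models (order-sensitive)."""
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if [r.id for r in a.reactions] != [r.id for r in b.reactions]:
        return False
    if sorted(a.genes) != sorted(b.genes):
        return False
    if a.biomass_reaction_id != b.biomass_reaction_id:
        return False
    for ma, mb in zip(a.metabolites, b.metabolites):
        if (ma.compartment, ma.formula, ma.charge) != (mb.compartment, mb.formula, mb.charge):
            return False
    for ra, rb in zip(a.reactions, b.reactions):
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
        keys = set(ra.stoichiometry) | set(rb.stoichiometry)
        for k in keys:
            if abs(ra.stoichiometry.get(k, 0.0) - rb.stoichiometry.get(k, 0.0)) > tol:
                return False
        ga = ra.gpr.to_string() if ra.gpr else ""
        gb = rb.gpr.to_string() if rb.gpr else ""
        if ga != gb:
            return False
    return True
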