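"""Model quality control.

Three audits used while curating a draft reconstruction:

* dead-end detection — a metabolite that is only produced or only consumed
  (reversible reactions count both ways) marks a gap in the network;
* element/charge balance — the signed sum of element counts over a
  reaction's stoichiometry must vanish; a deficit of exactly k protons
  suggests the common database error of a dropped H⁺;
* redundancy — duplicate reactions (identical stoichiometry up to a scalar
  multiple and direction) and isolated reactions (all of whose metabolites
  occur nowhere else).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MetabolicModel, Reaction, infer_category

#: Dead-end classifier labels, mutually exclusive per metabolite instance.
DEADEND_LABELS = (
    "is_deadend",
    "may_need_transport",
    "oneSub_Product",
    "ManySub_Product",
    "ok",
)

_DUP_TOL = 1e-9


@dataclass
class DeadendReport:
    """Per-metabolite dead-end classification.

    ``labels`` assigns every metabolite instance one label; ``deadends``
    lists the dead-end instances (including those labelled
    may_need_transport, which are dead-ends whose base metabolite exists in
    several compartments and may simply lack a transporter);
    ``deadend_reactions`` lists the reactions containing a dead-end.
    """

    labels: dict[str, str] = field(default_factory=dict)
    deadends: list[str] = field(default_factory=list)
    deadend_reactions: list[str] = field(default_factory=list)


@dataclass
class BalanceEntry:
    """Balance audit of one reaction."""

    reaction_id: str
    status: str  # "balanced" | "unbalanced" | "skipped" | "unauditable"
    element_deficit: dict[str, float] = field(default_factory=dict)
    charge_deficit: float = 0.0
    suggested_fix: str | None = None

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


@dataclass
class BalanceReport:
    entries: dict[str, BalanceEntry] = field(default_factory=dict)

    @property
    def all_balanced(self) -> bool:
        return all(
            e.status in ("balanced", "skipped") for e in self.entries.values()
        )


@dataclass
class RedundancyReport:
    duplicate_groups: list[list[str]] = field(default_factory=list)
    isolated: list[str] = field(default_factory=list)


def find_deadends(
    model: MetabolicModel, exclude_exchange: bool = True
) -> DeadendReport:
    """Classify every metabolite instance of the network.

    A metabolite is *producible* if some reaction makes it (positive
    coefficient, or any participation in a reversible reaction) and
    *consumable* analogously; a participating metabolite that is not both
    is a dead-end.  Non-dead-ends touching only reversible reactions are
    flagged oneSub_Product (exactly one) or ManySub_Product (two or more) —
    their net direction is undetermined, which is worth a curator's look.
    Dead-ends whose base metabolite exists in other compartments are
    labelled may_need_transport instead of is_deadend.

    Exchange reactions are ignored by default: an open exchange makes its
    metabolite trivially producible and consumable, hiding genuine gaps in
    the internal pathways.  The boundary species themselves (metabolites
    touched by an exchange) are likewise not reportable as dead-ends —
    the environment supplies and absorbs them — and are labelled ok.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    n_rev: dict[str, int] = {}
    n_irr: dict[str, int] = {}
    touching: dict[str, list[str]] = {}
    boundary: set[str] = set()
    for r in model.reactions:
        if exclude_exchange and infer_category(r, model) == "exchange":
            boundary.update(r.metabolite_ids())
            continue
        for mid, coef in r.stoichiometry.items():
            if coef == 0:
                continue
            touching.setdefault(mid, []).append(r.id)
            if r.reversible:
                producible.add(mid)
                consumable.add(mid)
                n_rev[mid] = n_rev.get(mid, 0) + 1
            else:
                n_irr[mid] = n_irr.get(mid, 0) + 1
                (producible if coef > 0 else consumable).add(mid)

    compartments_of_base: dict[str, set[str]] = {}
    for m in model.metabolites:
        compartments_of_base.setdefault(m.base_id, set()).add(m.compartment)

    report = DeadendReport()
    deadend_rxns: set[str] = set()
    for m in model.metabolites:
        mid = m.id
        if mid not in touching:
            report.labels[mid] = "ok"  # orphan species: no reaction to gap
            continue
        if mid in boundary:
            report.labels[mid] = "ok"
            continue
        if not (mid in producible and mid in consumable):
            multi = len(compartments_of_base[m.base_id]) > 1
            report.labels[mid] = "may_need_transport" if multi else "is_deadend"
            report.deadends.append(mid)
            deadend_rxns.update(touching[mid])
        elif n_irr.get(mid, 0) == 0 and n_rev.get(mid, 0) == 1:
            report.labels[mid] = "oneSub_Product"
        elif n_irr.get(mid, 0) == 0 and n_rev.get(mid, 0) >= 2:
            report.labels[mid] = "ManySub_Product"
        else:
            report.labels[mid] = "ok"
    report.deadends.sort()
    report.deadend_reactions = sorted(deadend_rxns)
    return report


def check_balance(reaction: Reaction, model: MetabolicModel) -> BalanceEntry:
    """Audit one reaction for element and charge balance.

    Exchange and biomass reactions are intrinsically one-sided and are
    skipped; reactions whose metabolites lack formula or charge are
    unauditable rather than failures.  The deficit is Σ coefficient ×
    count, so a positive H deficit means the products carry surplus
    hydrogen.
    """
    cat = infer_category(reaction, model)
    if cat in ("exchange", "biomass"):
        return BalanceEntry(reaction.id, "skipped")
    mets = model.metabolite_index
    deficit: dict[str, float] = {}
    charge = 0.0
    for mid, coef in reaction.stoichiometry.items():
        if coef == 0:
            continue
        m = mets[mid]
        if m.formula is None or m.charge is None:
            return BalanceEntry(reaction.id, "unauditable")
        for el, n in m.formula.items():
            deficit[el] = deficit.get(el, 0.0) + coef * n
        charge += coef * m.charge
    deficit = {el: v for el, v in deficit.items() if abs(v) > 1e-9}
    if not deficit and abs(charge) <= 1e-9:
        return BalanceEntry(reaction.id, "balanced")
    fix = None
    if set(deficit) == {"H"} and abs(deficit["H"] - charge) <= 1e-9:
        k = deficit["H"]
        side = "substrate" if k > 0 else "product"
        fix = f"add {abs(k):g} proton(s) on the {side} side"
    return BalanceEntry(reaction.id, "unbalanced", deficit, charge, fix)


def check_model_balance(model: MetabolicModel) -> BalanceReport:
    return BalanceReport(
        entries={r.id: check_balance(r, model) for r in model.reactions}
    )


def _normalized_key(reaction: Reaction) -> tuple:
    items = sorted(
        (mid, coef) for mid, coef in reaction.stoichiometry.items() if coef != 0
    )
    ref = items[0][1]  # coefficient of lexicographically first metabolite
    return tuple((mid, round(coef / ref, 9)) for mid, coef in items)


def find_redundant(model: MetabolicModel) -> RedundancyReport:
    """Detect duplicate reaction groups and isolated reactions.

    Duplicates share stoichiometry up to a positive or negative scalar
    (a flipped copy of a reaction counts); grouping compares stoichiometric
    vectors normalized by the leading coefficient, within 1e-9.  Isolated
    reactions are those all of whose metabolites occur in no other
    reaction — together with their metabolites they form a disconnected
    fragment.
    """
    groups: dict[tuple, list[str]] = {}
    for r in model.reactions:
        if not r.stoichiometry:
            continue
        groups.setdefault(_normalized_key(r), []).append(r.id)
    duplicate_groups = sorted(sorted(g) for g in groups.values() if len(g) > 1)

    n_touching: dict[str, int] = {}
    for r in model.reactions:
        for mid in r.metabolite_ids():
            n_touching[mid] = n_touching.get(mid, 0) + 1
    isolated = sorted(
        r.id
        for r in model.reactions
        if r.stoichiometry
        and all(n_touching[mid] == 1 for mid in r.metabolite_ids())
    )
    return RedundancyReport(duplicate_groups=duplicate_groups, isolated=isolated)
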