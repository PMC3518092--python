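"""Readers and writers: SBML (Level 3 + fbc preferred, Level 2 with
COBRA-style notes accepted), a tabular dialect, and medium files.

The tabular dialect is two UTF-8 delimited files:

``reactions.tsv``
    columns ``id, equation, lb, ub, gpr, category, name``; the equation
    grammar is ``2 a[c] + b[c] <=> 3 d[m]`` with ``<=>`` marking reversible
    and ``->`` irreversible reactions; either side may be empty (exchange
    reactions: ``glc[e] <=>``).

``metabolites.tsv``
    columns ``id, name, compartment, formula, charge``.

Metabolite ids carry their compartment as a bracketed suffix (``glc[e]``);
in SBML the compartment attribute is authoritative and the suffix is
re-derived on read.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Mapping

import libsbml
import pandas as pd
import yaml

from .gpr import BoolOp, Gene, GprExpression, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    formula_to_string,
    parse_formula,
)


class SbmlReadError(ValueError):
    """Raised for malformed or unsupported SBML input."""


# ---------------------------------------------------------------------------
# equation grammar
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 a[c] + b[c] <=> d[m]`` into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    reversible = arrow in ("<=>", "<->")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s\+\s|^\+\s|\s\+$", side):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+(.+)$", term)
            if m:
                coef, mid = float(m.group(1)), m.group(2).strip()
            else:
                coef, mid = 1.0, term
            if not mid or " " in mid:
                raise ValueError(f"cannot parse term {term!r} in equation {text!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ValueError(f"equation {text!r} has empty stoichiometry")
    return stoich, reversible


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            coef = abs(coef)
            parts.append(mid if coef == 1 else f"{coef:g} {mid}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------

def read_tabular(reactions_path, metabolites_path, sep: str = "\t") -> MetabolicModel:
    """Read a model from the two-file tabular dialect."""
    mets_df = pd.read_csv(metabolites_path, sep=sep, dtype=str).fillna("")
    rxns_df = pd.read_csv(reactions_path, sep=sep, dtype=str).fillna("")
    metabolites = []
    for _, row in mets_df.iterrows():
        metabolites.append(
            Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                compartment=row["compartment"],
                formula=parse_formula(row.get("formula", "")),
                charge=int(row["charge"]) if str(row.get("charge", "")).strip() else None,
            )
        )
    known = {m.id for m in metabolites}
    reactions = []
    biomass_id = None
    for i, row in rxns_df.iterrows():
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ValueError as exc:
            raise ValueError(f"row {i} (reaction {row.get('id')!r}): {exc}") from exc
        missing = sorted(set(stoich) - known)
        if missing:
            raise ValueError(
                f"row {i} (reaction {row['id']!r}) references undeclared "
                f"metabolites {missing}"
            )
        lb_s, ub_s = str(row.get("lb", "")).strip(), str(row.get("ub", "")).strip()
        lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if reversible else 0.0)
        ub = float(ub_s) if ub_s else DEFAULT_BOUND
        category = str(row.get("category", "")).strip() or None
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(row.get("gpr", "")),
                category=category,
                name=row.get("name", ""),
            )
        )
        if category == "biomass" and biomass_id is None:
            biomass_id = row["id"]
    genes = sorted({g for r in reactions for g in r.genes})
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=biomass_id,
    )
    model.validate()
    return model


def write_tabular(model: MetabolicModel, reactions_path, metabolites_path,
                  sep: str = "\t") -> None:
    mets = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [formula_to_string(m.formula) for m in model.metabolites],
            "charge": ["" if m.charge is None else m.charge for m in model.metabolites],
        }
    )
    rxns = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "equation": [
                format_equation(r.stoichiometry, r.reversible) for r in model.reactions
            ],
            "lb": [r.lower_bound for r in model.reactions],
            "ub": [r.upper_bound for r in model.reactions],
            "gpr": [r.gpr.to_string() if r.gpr else "" for r in model.reactions],
            "category": [r.category or "" for r in model.reactions],
            "name": [r.name for r in model.reactions],
        }
    )
    mets.to_csv(metabolites_path, sep=sep, index=False)
    rxns.to_csv(reactions_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    s = _SID_BAD.sub("_", raw)
    if not s or s[0].isdigit():
        s = "_" + s
    return prefix + s


def _met_sid(m: Metabolite) -> str:
    return _sid("M_", m.base_id) + f"_{m.compartment}"


def _assoc_to_expr(assoc, label_of: dict[str, str]) -> GprExpression | None:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = assoc.getGeneProduct()
        return Gene(label_of.get(gp, gp))
    children = [
        _assoc_to_expr(assoc.getAssociation(i), label_of)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    return BoolOp("and" if assoc.isFbcAnd() else "or", tuple(children))


def _notes_field(notes: str, key: str) -> str | None:
    m = re.search(rf"{key}\s*:\s*([^<\n]*)", notes)
    return m.group(1).strip() if m else None


def read_sbml(path) -> MetabolicModel:
    """Read an SBML model (Level 3 + fbc, or Level 2 with COBRA notes)."""
    path = str(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors() > 0:
        fatal = [
            doc.getError(i)
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if fatal:
            e = fatal[0]
            raise SbmlReadError(
                f"{path}: SBML parse error at line {e.getLine()}: {e.getMessage()}"
            )
    smod = doc.getModel()
    if smod is None:
        raise SbmlReadError(f"{path}: no <model> element found")
    fbc = smod.getPlugin("fbc")

    compartments = {}
    for i in range(smod.getNumCompartments()):
        comp = smod.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()

    label_of: dict[str, str] = {}
    genes: list[str] = []
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            label_of[gp.getId()] = label
            genes.append(label)

    metabolites = []
    species_mid: dict[str, str] = {}
    for i in range(smod.getNumSpecies()):
        sp = smod.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the environment, not the network
        comp = sp.getCompartment()
        base = re.sub("^M_", "", sp.getId())
        base = re.sub(f"_{re.escape(comp)}$", "", base)
        mid = f"{base}[{comp}]"
        formula = None
        charge = None
        spf = sp.getPlugin("fbc")
        if spf is not None:
            if spf.isSetChemicalFormula():
                formula = parse_formula(spf.getChemicalFormula())
            if spf.isSetCharge():
                charge = spf.getCharge()
        if formula is None or charge is None:
            notes = sp.getNotesString() if sp.isSetNotes() else ""
            if formula is None:
                f = _notes_field(notes, "FORMULA")
                if f:
                    formula = parse_formula(f)
            if charge is None:
                ch = _notes_field(notes, "CHARGE")
                if ch:
                    try:
                        charge = int(float(ch))
                    except ValueError:
                        pass
        metabolites.append(
            Metabolite(
                id=mid, name=sp.getName() or "", compartment=comp,
                formula=formula, charge=charge,
            )
        )
        species_mid[sp.getId()] = mid

    params = {
        smod.getParameter(i).getId(): smod.getParameter(i).getValue()
        for i in range(smod.getNumParameters())
    }

    reactions = []
    biomass_id = None
    objective: dict[str, float] = {}
    for i in range(smod.getNumReactions()):
        rx = smod.getReaction(i)
        rid = re.sub("^R_", "", rx.getId())
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            mid = species_mid.get(sr.getSpecies())
            if mid is not None:
                stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            mid = species_mid.get(sr.getSpecies())
            if mid is not None:
                stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        if not stoich:
            continue

        rev = rx.getReversible()
        lb = ub = None
        rxf = rx.getPlugin("fbc")
        if rxf is not None and rxf.isSetLowerFluxBound():
            lb = params.get(rxf.getLowerFluxBound())
            ub = params.get(rxf.getUpperFluxBound())
        if lb is None and rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for k in range(kl.getNumParameters()):
                p = kl.getParameter(k)
                if p.getId().upper() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId().upper() == "UPPER_BOUND":
                    ub = p.getValue()
        if lb is None or not math.isfinite(lb):
            lb = -DEFAULT_BOUND if rev else 0.0
        if ub is None or not math.isfinite(ub):
            ub = DEFAULT_BOUND
        lb = max(lb, -DEFAULT_BOUND) if not math.isfinite(lb) else lb
        gpr = None
        if rxf is not None and rxf.isSetGeneProductAssociation():
            gpr = _assoc_to_expr(
                rxf.getGeneProductAssociation().getAssociation(), label_of
            )
        notes = rx.getNotesString() if rx.isSetNotes() else ""
        if gpr is None:
            ga = _notes_field(notes, "GENE_ASSOCIATION")
            if ga:
                gpr = parse_gpr(ga)
        category = _notes_field(notes, "CATEGORY")
        reactions.append(
            Reaction(
                id=rid, stoichiometry=stoich, lower_bound=float(lb),
                upper_bound=float(ub), gpr=gpr, category=category,
                name=rx.getName() or "",
            )
        )
        if "biomass" in rid.lower() or category == "biomass":
            biomass_id = biomass_id or rid

    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(0)
        for k in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(k)
            rid = re.sub("^R_", "", fo.getReaction())
            objective[rid] = fo.getCoefficient()
        if len(objective) == 1 and biomass_id is None:
            biomass_id = next(iter(objective))

    if not genes:
        genes = sorted({g for r in reactions for g in r.genes})
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(set(genes)),
        biomass_reaction_id=biomass_id,
        objective_coefficients=objective,
        id=smod.getId() or "model",
        compartments=compartments or None or {},
    )
    if not compartments:
        model.compartments = {m.compartment: m.compartment for m in metabolites}
    try:
        model.validate()
    except ModelValidationError as exc:
        raise SbmlReadError(f"{path}: {exc}") from exc
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Write a model as SBML Level 3 Version 1 with the fbc (v2) package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smod = doc.createModel()
    smod.setId(_SID_BAD.sub("_", model.id) or "model")
    fbc = smod.getPlugin("fbc")
    fbc.setStrict(False)

    for cid, cname in model.compartments.items():
        comp = smod.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    gene_sid: dict[str, str] = {}
    for g in sorted(model.genes):
        gp = fbc.createGeneProduct()
        sid = _sid("G_", g)
        gp.setId(sid)
        gp.setLabel(g)
        gene_sid[g] = sid

    met_sid: dict[str, str] = {}
    for m in model.metabolites:
        sp = smod.createSpecies()
        sid = _met_sid(m)
        met_sid[m.id] = sid
        sp.setId(sid)
        sp.setName(m.name or m.base_id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        spf = sp.getPlugin("fbc")
        if m.formula is not None:
            spf.setChemicalFormula(formula_to_string(m.formula))
        if m.charge is not None:
            spf.setCharge(int(m.charge))

    bound_param: dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_param:
            pid = f"fb_{len(bound_param)}"
            p = smod.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    for r in model.reactions:
        rx = smod.createReaction()
        rx.setId(_sid("R_", r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                sr = rx.createReactant()
            elif coef > 0:
                sr = rx.createProduct()
            else:
                continue
            sr.setSpecies(met_sid[mid])
            sr.setStoichiometry(abs(float(coef)))
            sr.setConstant(True)
        rxf = rx.getPlugin("fbc")
        rxf.setLowerFluxBound(param_for(r.lower_bound))
        rxf.setUpperFluxBound(param_for(r.upper_bound))
        if r.gpr is not None:
            gpa = rxf.createGeneProductAssociation()
            infix = _expr_to_fbc_infix(r.gpr, gene_sid)
            # usingId=True: tokens are the gene-product SIds created above
            gpa.setAssociation(infix, True, False)
        if r.category:
            rx.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>CATEGORY: {r.category}</p></body>"
            )

    if model.objective_coefficients:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, coef in model.objective_coefficients.items():
            fo = obj.createFluxObjective()
            fo.setReaction(_sid("R_", rid))
            fo.setCoefficient(float(coef))
        fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _expr_to_fbc_infix(expr: GprExpression, gene_sid: dict[str, str]) -> str:
    if isinstance(expr, Gene):
        return gene_sid.get(expr.id, _sid("G_", expr.id))
    parts = [f"({_expr_to_fbc_infix(a, gene_sid)})" for a in expr.args]
    return f" {expr.op} ".join(parts)


# ---------------------------------------------------------------------------
# medium files
# ---------------------------------------------------------------------------

def read_medium(path) -> dict[str, tuple[float, float]]:
    """Read a medium (exchange id → (lb, ub)) from YAML or TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        out = {}
        for rid, bounds in raw.items():
            if isinstance(bounds, (int, float)):
                out[rid] = (float(bounds), DEFAULT_BOUND)
            else:
                out[rid] = (float(bounds[0]), float(bounds[1]))
        return out
    df = pd.read_csv(path, sep="\t")
    return {
        row["exchange"]: (float(row["lb"]), float(row["ub"]))
        for _, row in df.iterrows()
    }


def write_medium(medium: Mapping[str, tuple[float, float]], path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = {rid: [float(lb), float(ub)] for rid, (lb, ub) in sorted(medium.items())}
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        pd.DataFrame(
            [
                {"exchange": rid, "lb": lb, "ub": ub}
                for rid, (lb, ub) in sorted(medium.items())
            ]
        ).to_csv(path, sep="\t", index=False)
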