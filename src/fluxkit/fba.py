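"""Flux balance analysis.

FBA poses metabolism as a linear program: find a flux vector v (one entry
per reaction, mmol·gDCW⁻¹·h⁻¹) maximizing an objective cᵀv — typically the
biomass reaction, whose flux is the specific growth rate in h⁻¹ — subject
to steady-state mass balance S·v = 0 and bounds α ≤ v ≤ β encoding
reaction directionality and capacity.  Solved with the HiGHS simplex
through scipy, which returns an optimal vertex of the flux polytope.

Maintenance energy enters in two places: a non-growth-associated demand
(NGAM, mmol ATP·gDCW⁻¹·h⁻¹) pinned on an ATP-hydrolysis reaction, and a
growth-associated demand (GAM, mmol ATP·gDCW⁻¹) folded into the biomass
reaction.  Both are estimated from chemostat data: the ATP production rate
is linear in the dilution rate D with slope GAM and intercept NGAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, Reaction, build_stoichiometric_matrix

#: LP feasibility tolerance handed to HiGHS.
SOLVER_TOL = 1e-9
#: Fluxes below this magnitude are reported as zero.
ZERO_TOL = 1e-6


@dataclass
class FluxResult:
    """Outcome of one FBA solve."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class MaintenanceParams:
    """Maintenance-energy parameters.

    ngam: mmol ATP·gDCW⁻¹·h⁻¹; gam: mmol ATP·gDCW⁻¹; atp_yield: mol ATP
    produced per mol substrate fully oxidized (used during estimation).
    """

    ngam: float
    gam: float
    atp_yield: float = 18.5

    def __post_init__(self) -> None:
        if self.ngam < 0 or self.gam < 0:
            raise ValueError("maintenance parameters must be non-negative")


class LpData:
    """Cached arrays for repeated LP solves over one model structure.

    Bounds can be overridden per solve, which is what gene deletions, media
    changes and FVA all reduce to; the stoichiometric matrix is built once.
    """

    def __init__(self, model: MetabolicModel):
        self.S, self.met_ids, self.rxn_ids = build_stoichiometric_matrix(model)
        self.col_of = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.lb = np.array([r.lower_bound for r in model.reactions], float)
        self.ub = np.array([r.upper_bound for r in model.reactions], float)

    def objective_vector(
        self, objective: str | Mapping[str, float]
    ) -> np.ndarray:
        c = np.zeros(len(self.rxn_ids))
        if isinstance(objective, str):
            if objective not in self.col_of:
                raise KeyError(f"objective reaction {objective!r} not in model")
            c[self.col_of[objective]] = 1.0
        else:
            for rid, coef in objective.items():
                if rid not in self.col_of:
                    raise KeyError(f"objective reaction {rid!r} not in model")
                c[self.col_of[rid]] = float(coef)
        return c

    def solve(
        self,
        c: np.ndarray,
        sense: str = "max",
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
        extra_A_ub: sparse.spmatrix | np.ndarray | None = None,
        extra_b_ub: np.ndarray | None = None,
    ) -> tuple[str, float | None, np.ndarray | None]:
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={
                "presolve": True,
                "primal_feasibility_tolerance": SOLVER_TOL,
                "dual_feasibility_tolerance": SOLVER_TOL,
            },
        )
        if res.status == 0:
            return "optimal", sign * res.fun, res.x
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        raise RuntimeError(f"LP solver failure: {res.message}")


def solve_fba(
    model: MetabolicModel,
    objective: str | Mapping[str, float] | None = None,
    sense: str = "max",
) -> FluxResult:
    """Solve max (or min) cᵀv subject to S·v = 0, α ≤ v ≤ β.

    ``objective`` is a reaction id or a reaction→coefficient mapping;
    by default the model's own objective (usually biomass) is used.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if objective is None:
        objective = model.objective_coefficients or model.biomass_reaction_id
        if not objective:
            raise ValueError("model declares no objective and none was given")
    lp = LpData(model)
    c = lp.objective_vector(objective)
    status, z, x = lp.solve(c, sense=sense)
    if status != "optimal":
        return FluxResult(status=status)
    fluxes = {rid: float(v) for rid, v in zip(lp.rxn_ids, x)}
    return FluxResult(status="optimal", objective_value=float(z), fluxes=fluxes)


def apply_medium(
    model: MetabolicModel,
    medium: Mapping[str, tuple[float, float]],
    close_other_exchanges: bool = True,
) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set from a medium.

    Exchanges absent from the medium have uptake closed (lb = 0) when
    ``close_other_exchanges``; secretion stays open.
    """
    from .model import infer_category

    out = model.copy()
    for r in out.reactions:
        if r.id in medium:
            r.lower_bound, r.upper_bound = map(float, medium[r.id])
        elif close_other_exchanges and infer_category(r, out) == "exchange":
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def apply_maintenance(
    model: MetabolicModel,
    params: MaintenanceParams,
    maintenance_reaction_id: str = "ATPM",
    energy_ids: Mapping[str, str] | None = None,
) -> MetabolicModel:
    """Return a copy with maintenance demands imposed.

    The ATP-hydrolysis maintenance reaction has both bounds pinned to NGAM
    (it must run at exactly that rate); it is created as
    ATP + H₂O → ADP + Pi + H from ``energy_ids`` if absent.  The biomass
    reaction's ATP/ADP/Pi terms are shifted so that the growth-associated
    ATP demand equals GAM per unit biomass.
    """
    out = model.copy()
    rids = {r.id for r in out.reactions}
    roles = dict(energy_ids or {})
    if maintenance_reaction_id not in rids:
        known = {m.id for m in out.metabolites}
        stoich: dict[str, float] = {}
        for role, sign in (("atp", -1.0), ("h2o", -1.0), ("adp", 1.0),
                           ("pi", 1.0), ("h", 1.0)):
            mid = roles.get(role)
            if mid in known:
                stoich[mid] = sign
        if not stoich:
            raise KeyError(
                "no maintenance reaction in model and no ATP metabolite ids "
                "given to create one"
            )
        out.reactions.append(
            Reaction(
                id=maintenance_reaction_id, stoichiometry=stoich,
                lower_bound=0.0, upper_bound=0.0, category="metabolic",
                name="ATP maintenance requirement",
            )
        )
    atpm = out.get_reaction(maintenance_reaction_id)
    atpm.lower_bound = atpm.upper_bound = float(params.ngam)

    if out.biomass_reaction_id is not None and params.gam >= 0 and roles:
        biomass = out.get_reaction(out.biomass_reaction_id)
        known = {m.id for m in out.metabolites}
        current = -biomass.stoichiometry.get(roles.get("atp", ""), 0.0)
        delta = float(params.gam) - current
        if abs(delta) > 0:
            for role, sign in (("atp", -1.0), ("h2o", -1.0), ("adp", 1.0),
                               ("pi", 1.0), ("h", 1.0)):
                mid = roles.get(role)
                if mid in known:
                    biomass.stoichiometry[mid] = (
                        biomass.stoichiometry.get(mid, 0.0) + sign * delta
                    )
    return out


def estimate_maintenance(
    chemostat: Sequence[tuple[float, float]],
    atp_yield: float = 18.5,
) -> MaintenanceParams:
    """Estimate GAM and NGAM from chemostat (dilution rate, uptake) pairs.

    The ATP production rate, atp_yield × substrate uptake, is regressed on
    the dilution rate D (= specific growth rate at steady state); the slope
    is GAM and the intercept NGAM.  Requires ≥2 distinct dilution rates.
    """
    data = np.asarray(chemostat, float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need at least two (dilution rate, uptake) pairs")
    D, uptake = data[:, 0], data[:, 1]
    if np.ptp(D) == 0:
        raise ValueError("dilution rates are all identical; cannot fit a line")
    atp_rate = atp_yield * uptake
    slope, intercept = np.polyfit(D, atp_rate, 1)
    return MaintenanceParams(
        ngam=max(float(intercept), 0.0), gam=max(float(slope), 0.0),
        atp_yield=atp_yield,
    )
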