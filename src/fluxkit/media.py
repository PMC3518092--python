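"""Minimal-medium determination and carbon-substrate screening.

A medium is a map from exchange-reaction ids to (lb, ub) bounds; negative
lower bounds permit uptake.  The minimal medium is found by greedy
elimination: open every candidate exchange, then close candidates one at a
time (deterministic lexicographic order) and keep each closed only if
growth survives.  The result is locally minimal — closing any retained
component abolishes growth — though not necessarily of globally minimum
cardinality.

Substrate screening replaces the carbon source of a base medium with each
test substrate in turn and asks whether biomass flux clears a threshold;
predictions are compared against observed assimilation calls with the
GN/NG bookkeeping (GN: grows in experiment, not in silico; NG: the
reverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fba import ZERO_TOL, apply_medium, solve_fba
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, infer_category

#: Medium type: exchange reaction id → (lower bound, upper bound).
Medium = dict[str, tuple[float, float]]

DEFAULT_UPTAKE_BOUND = 20.0
DEFAULT_GROWTH_THRESHOLD = 1e-6


@dataclass
class SubstrateCall:
    substrate: str
    growth: float
    predicted: bool
    observed: bool | None = None
    reason: str = ""

    @property
    def agreement_class(self) -> str | None:
        """TP/TN when prediction matches observation, GN/NG otherwise."""
        if self.observed is None:
            return None
        if self.observed and self.predicted:
            return "TP"
        if not self.observed and not self.predicted:
            return "TN"
        return "GN" if self.observed else "NG"


@dataclass
class SubstrateScreenResult:
    calls: list[SubstrateCall] = field(default_factory=list)

    def call_for(self, substrate: str) -> SubstrateCall:
        for c in self.calls:
            if c.substrate == substrate:
                return c
        raise KeyError(substrate)


@dataclass
class ScreenComparison:
    accuracy: float
    n_agree: int
    n_total: int
    gn: list[str] = field(default_factory=list)
    ng: list[str] = field(default_factory=list)


def _growth(model: MetabolicModel, medium: Medium) -> float:
    res = solve_fba(apply_medium(model, medium))
    return res.objective_value if res.optimal else 0.0


def determine_minimal_media(
    model: MetabolicModel,
    carbon_exchange: str,
    candidate_exchanges: Sequence[str],
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    carbon_lb: float = -DEFAULT_UPTAKE_BOUND,
    free_exchanges: Sequence[str] = (),
) -> Medium:
    """Greedy minimal-medium search.

    ``free_exchanges`` (typically water, CO₂ and proton) are always
    retained as freely exchangeable and are not subject to elimination.
    Raises if the model cannot grow even with the full candidate pool open.
    """
    if carbon_exchange not in candidate_exchanges:
        raise ValueError("carbon exchange must be among the candidates")
    rids = {r.id for r in model.reactions}
    missing = sorted(set(candidate_exchanges) - rids)
    if missing:
        raise KeyError(f"candidate exchanges not in model: {missing}")

    medium: Medium = {rid: (-DEFAULT_BOUND, DEFAULT_BOUND) for rid in candidate_exchanges}
    for rid in free_exchanges:
        medium[rid] = (-DEFAULT_BOUND, DEFAULT_BOUND)
    medium[carbon_exchange] = (carbon_lb, DEFAULT_BOUND)

    if _growth(model, medium) <= growth_threshold:
        raise ValueError("model cannot grow on candidate pool")

    keep_always = set(free_exchanges) | {carbon_exchange}
    for rid in sorted(candidate_exchanges):
        if rid in keep_always:
            continue
        trial = dict(medium)
        trial[rid] = (0.0, DEFAULT_BOUND)  # close uptake, keep secretion open
        if _growth(model, trial) > growth_threshold:
            medium = trial
    minimal = {
        rid: bounds for rid, bounds in medium.items() if bounds[0] < 0
    }
    # final verification solve
    if _growth(model, minimal) <= growth_threshold:
        raise RuntimeError("greedy elimination produced a non-growing medium")
    return minimal


def screen_substrates(
    model: MetabolicModel,
    base_medium: Medium,
    substrates: Sequence[str],
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    observed: Mapping[str, bool] | None = None,
    add_exchange: bool = True,
    add_transport: bool = False,
) -> SubstrateScreenResult:
    """Test growth on each substrate as the sole carbon source.

    ``substrates`` are extracellular metabolite ids.  A missing exchange
    reaction is created when ``add_exchange``; a naive diffusion transport
    into the cytoplasm is only created under ``add_transport`` (off by
    default — transporters are curation decisions, not screening ones).
    A substrate absent from the model is recorded as predicted negative
    with reason "no pathway".
    """
    observed = dict(observed or {})
    result = SubstrateScreenResult()
    for sub in substrates:
        work = model.copy()
        known = {m.id for m in work.metabolites}
        reason = ""
        if sub not in known:
            if add_transport:
                # model the substrate as a fresh extracellular species
                work.metabolites.append(Metabolite(id=sub, compartment="e"))
            else:
                result.calls.append(
                    SubstrateCall(sub, 0.0, False, observed.get(sub), "no pathway")
                )
                continue
        ex_id = _ensure_exchange(work, sub, create=add_exchange)
        if ex_id is None:
            result.calls.append(
                SubstrateCall(sub, 0.0, False, observed.get(sub), "no exchange")
            )
            continue
        if add_transport:
            _ensure_transport(work, sub)
        medium = dict(base_medium)
        medium[ex_id] = (-abs(uptake_bound), DEFAULT_BOUND)
        growth = _growth(work, medium)
        result.calls.append(
            SubstrateCall(
                sub, growth, growth > growth_threshold, observed.get(sub), reason
            )
        )
    return result


def _ensure_exchange(model: MetabolicModel, met_id: str, create: bool) -> str | None:
    for r in model.reactions:
        if infer_category(r, model) == "exchange" and r.metabolite_ids() == [met_id]:
            return r.id
    if not create:
        return None
    ex_id = f"EX_{met_id.replace('[', '_').replace(']', '')}"
    model.reactions.append(
        Reaction(
            id=ex_id, stoichiometry={met_id: -1.0}, lower_bound=0.0,
            upper_bound=DEFAULT_BOUND, category="exchange",
            name=f"{met_id} exchange",
        )
    )
    return ex_id


def _ensure_transport(model: MetabolicModel, met_id: str) -> None:
    met = model.get_metabolite(met_id)
    base = met.base_id
    cyto_id = f"{base}[c]"
    known = {m.id for m in model.metabolites}
    if cyto_id not in known:
        model.metabolites.append(
            Metabolite(id=cyto_id, compartment="c", formula=met.formula,
                       charge=met.charge)
        )
    for r in model.reactions:
        cov = set(r.metabolite_ids())
        if cov == {met_id, cyto_id}:
            return
    model.reactions.append(
        Reaction(
            id=f"T_{base}_diff", stoichiometry={met_id: -1.0, cyto_id: 1.0},
            lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND,
            category="transport", name=f"{base} diffusion",
        )
    )


def compare_predictions(result: SubstrateScreenResult) -> ScreenComparison:
    """Accuracy of predictions against observations, with GN/NG lists."""
    scored = [c for c in result.calls if c.observed is not None]
    if not scored:
        raise ValueError("no observed labels to compare against")
    n_agree = sum(c.agreement_class in ("TP", "TN") for c in scored)
    gn = sorted(c.substrate for c in scored if c.agreement_class == "GN")
    ng = sorted(c.substrate for c in scored if c.agreement_class == "NG")
    return ScreenComparison(
        accuracy=n_agree / len(scored), n_agree=n_agree, n_total=len(scored),
        gn=gn, ng=ng,
    )
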