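"""Flux variability analysis and the SD knockout-ranking score.

FVA fixes the objective at a fraction γ of its FBA optimum (cᵀv ≥ γ·Z_max)
and then minimizes and maximizes each reaction's flux in turn — 2n LP
solves — yielding a [v_min, v_max] interval per reaction.  γ = 1 probes
the optimal face of the flux polytope; γ < 1 a suboptimal band.

The SD score summarizes how much a single-gene knockout redistributes
flux: for each reaction whose wild-type bounds are both nonzero, the
mutant-vs-wild-type deviations

    Δmax_i = |v_max,mut − v_max,wt| / |v_max,wt|
    Δmin_i = |v_min,mut − v_min,wt| / |v_min,wt|

are averaged, SD = mean_i (Δmax_i + Δmin_i) / 2, over the computable
subset (reactions with a zero wild-type bound are excluded and routed to
Group I/II discovery instead).  Genes with large SD globally rewire flux
and are candidate engineering targets.  Group I collects reactions whose
wild-type FVA *minimum* is zero but becomes nonzero in the mutant,
Group II the same for maxima — latent capabilities switched on by the
knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .fba import LpData, apply_medium
from .deletion import reactions_disabled_by
from .media import Medium
from .model import MetabolicModel

#: |wild-type bound| below this counts as "zero" (incomputable for SD).
WT_ZERO_TOL = 1e-9
#: mutant bound above this counts as genuinely activated.
ACTIVATION_TOL = 1e-6


@dataclass
class FvaRange:
    reaction_id: str
    v_min: float
    v_max: float


@dataclass
class FvaResult:
    """FVA ranges for every reaction at a fixed γ."""

    gamma: float
    z_max: float
    ranges: dict[str, FvaRange] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> FvaRange:
        return self.ranges[rid]


@dataclass
class SdScore:
    gene: str
    sd: float | None  # None when undefined (no computable reactions / infeasible)
    n_used: int
    status: str = "ok"  # "ok" | "undefined" | "infeasible"
    group1: list[tuple[str, str]] = field(default_factory=list)
    group2: list[tuple[str, str]] = field(default_factory=list)


def run_fva(
    model: MetabolicModel,
    medium: Medium | None = None,
    gamma: float = 1.0,
    reactions: Sequence[str] | None = None,
    _lp: LpData | None = None,
    _bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> FvaResult:
    """Compute [v_min, v_max] per reaction at objective fraction γ.

    Raises on γ outside [0, 1] or when the γ-constrained LP is infeasible
    (reported together with the Z_max that could not be sustained).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    work = apply_medium(model, medium) if medium else model
    lp = _lp if _lp is not None else LpData(work)
    lb, ub = _bounds if _bounds is not None else (lp.lb, lp.ub)
    c = lp.objective_vector(work.objective_coefficients or work.biomass_reaction_id)
    status, z_max, _ = lp.solve(c, sense="max", lb=lb, ub=ub)
    if status != "optimal" or z_max is None:
        raise RuntimeError(f"FBA optimum unavailable for FVA: status {status}")
    # objective floor: c^T v >= gamma * z_max  <=>  -c^T v <= -gamma * z_max
    A_ub = sparse.csr_matrix(-c.reshape(1, -1))
    b_ub = np.array([-gamma * z_max])
    result = FvaResult(gamma=gamma, z_max=z_max)
    targets = reactions if reactions is not None else lp.rxn_ids
    for rid in targets:
        j = lp.col_of[rid]
        cj = np.zeros(len(lp.rxn_ids))
        cj[j] = 1.0
        smin, vmin, _ = lp.solve(cj, "min", lb=lb, ub=ub,
                                 extra_A_ub=A_ub, extra_b_ub=b_ub)
        smax, vmax, _ = lp.solve(cj, "max", lb=lb, ub=ub,
                                 extra_A_ub=A_ub, extra_b_ub=b_ub)
        if smin != "optimal" or smax != "optimal":
            raise RuntimeError(
                f"FVA subproblem for {rid} at gamma={gamma} is {smin}/{smax} "
                f"(Z_max={z_max})"
            )
        result.ranges[rid] = FvaRange(rid, float(vmin), float(vmax))
    return result


def sd_score(
    wild: FvaResult | Mapping[str, FvaRange],
    mutant: FvaResult | Mapping[str, FvaRange],
) -> tuple[float | None, int]:
    """Average relative FVA-range deviation of a mutant from wild type.

    Returns (SD, n_used); SD is None when no reaction is computable
    (both wild-type bounds must be nonzero for a reaction to enter).
    """
    wr = wild.ranges if isinstance(wild, FvaResult) else dict(wild)
    mr = mutant.ranges if isinstance(mutant, FvaResult) else dict(mutant)
    if set(wr) != set(mr):
        raise ValueError("wild-type and mutant FVA cover different reactions")
    devs = []
    for rid, w in wr.items():
        if abs(w.v_max) <= WT_ZERO_TOL or abs(w.v_min) <= WT_ZERO_TOL:
            continue
        m = mr[rid]
        d_max = abs(m.v_max - w.v_max) / abs(w.v_max)
        d_min = abs(m.v_min - w.v_min) / abs(w.v_min)
        devs.append(0.5 * (d_max + d_min))
    if not devs:
        return None, 0
    return float(np.mean(devs)), len(devs)


def find_zero_to_nonzero(
    wild: FvaResult | Mapping[str, FvaRange],
    mutant: FvaResult | Mapping[str, FvaRange],
    gene: str,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Group I/II reaction-gene pairs activated by a knockout.

    Group I: wild-type v_min ≈ 0 but mutant |v_min| above the activation
    threshold; Group II analogously for v_max.
    """
    wr = wild.ranges if isinstance(wild, FvaResult) else dict(wild)
    mr = mutant.ranges if isinstance(mutant, FvaResult) else dict(mutant)
    if set(wr) != set(mr):
        raise ValueError("wild-type and mutant FVA cover different reactions")
    group1, group2 = [], []
    for rid in sorted(wr):
        w, m = wr[rid], mr[rid]
        if abs(w.v_min) <= WT_ZERO_TOL and abs(m.v_min) > ACTIVATION_TOL:
            group1.append((rid, gene))
        if abs(w.v_max) <= WT_ZERO_TOL and abs(m.v_max) > ACTIVATION_TOL:
            group2.append((rid, gene))
    return group1, group2


def rank_knockouts(
    model: MetabolicModel,
    medium: Medium | None = None,
    genes: Sequence[str] | None = None,
    gamma: float = 1.0,
) -> list[SdScore]:
    """Score and rank gene knockouts by descending SD.

    Wild-type FVA is computed once and reused.  Each mutant's FVA is run
    at γ times the *mutant's own* optimum (after a knockout the wild-type
    optimum is generally unreachable).  Mutants infeasible at γ — e.g.
    essential-gene knockouts that cannot grow at all — are recorded with
    status "infeasible" and rank last.  Ties break on gene id.
    """
    work = apply_medium(model, medium) if medium else model
    lp = LpData(work)
    wild = run_fva(work, gamma=gamma, _lp=lp)
    gene_list = list(genes) if genes is not None else sorted(work.genes)
    scores: list[SdScore] = []
    for gene in gene_list:
        disabled = reactions_disabled_by(work, {gene})
        if not disabled:
            # knockout leaves the network untouched: mutant ranges equal wild
            sd, n_used = sd_score(wild, wild)
            scores.append(SdScore(gene, 0.0 if sd is not None else None,
                                  n_used, "ok", [], []))
            continue
        lb = lp.lb.copy()
        ub = lp.ub.copy()
        for rid in disabled:
            j = lp.col_of[rid]
            lb[j] = ub[j] = 0.0
        try:
            mut = run_fva(work, gamma=gamma, _lp=lp, _bounds=(lb, ub))
        except RuntimeError:
            scores.append(SdScore(gene, None, 0, "infeasible", [], []))
            continue
        sd, n_used = sd_score(wild, mut)
        g1, g2 = find_zero_to_nonzero(wild, mut, gene)
        status = "ok" if sd is not None else "undefined"
        scores.append(SdScore(gene, sd, n_used, status, g1, g2))
    scores.sort(key=lambda s: (-(s.sd if s.sd is not None else -np.inf), s.gene))
    return scores
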