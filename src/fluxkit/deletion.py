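"""Single-gene knockout essentiality analysis.

Deleting a gene sets it False in every GPR rule; reactions whose rule then
evaluates False are disabled (bounds pinned to zero) and the FBA growth
optimum is recomputed.  The ratio of knockout to wild-type growth
classifies each gene as essential (ratio ≈ 0), partially essential
(strictly between) or non-essential (ratio ≈ 1).  Reactions with no GPR
are never disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fba import LpData, solve_fba, apply_medium
from .gpr import evaluate_gpr
from .media import Medium
from .model import MetabolicModel

#: ratio below eps_zero → essential; above 1 − eps_full → non-essential.
EPS_ZERO = 1e-6
EPS_FULL = 1e-3

LABELS = ("essential", "partially_essential", "non_essential")


@dataclass
class GeneResult:
    gene: str
    z_wt: float
    z_ko: float
    ratio: float
    label: str


@dataclass
class EssentialityReport:
    z_wt: float = 0.0
    results: dict[str, GeneResult] = field(default_factory=dict)

    def genes_with_label(self, label: str) -> list[str]:
        return sorted(g for g, r in self.results.items() if r.label == label)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.results.values():
            counts[r.label] += 1
        return counts


def classify(ratio: float, eps_zero: float = EPS_ZERO,
             eps_full: float = EPS_FULL) -> str:
    """Three-way essentiality call from a knockout/wild-type growth ratio."""
    if ratio < 0:
        raise ValueError("growth ratio cannot be negative")
    if ratio < eps_zero:
        return "essential"
    if ratio > 1.0 - eps_full:
        return "non_essential"
    return "partially_essential"


def reactions_disabled_by(model: MetabolicModel, deleted: set[str]) -> list[str]:
    """Reactions whose GPR evaluates False with ``deleted`` knocked out."""
    return [
        r.id
        for r in model.reactions
        if r.gpr is not None and not evaluate_gpr(r.gpr, deleted)
    ]


def single_gene_deletion(
    model: MetabolicModel,
    medium: Medium | None = None,
    eps_zero: float = EPS_ZERO,
    eps_full: float = EPS_FULL,
    genes: list[str] | None = None,
) -> EssentialityReport:
    """Knock out each gene in turn and record the growth ratio.

    The wild-type optimum Z_wt and every knockout are solved on the same
    medium; an infeasible knockout LP counts as zero growth.  Bounds are
    restored between genes.  Genes touching only reactions that stay
    enabled (e.g. through an isozyme) are non-essential by construction
    and skip the LP re-solve.
    """
    work = apply_medium(model, medium) if medium else model
    wt = solve_fba(work)
    if not wt.optimal or wt.objective_value is None or wt.objective_value <= 0:
        raise ValueError("wild type does not grow on the given medium")
    z_wt = wt.objective_value

    lp = LpData(work)
    c = lp.objective_vector(work.objective_coefficients or work.biomass_reaction_id)
    report = EssentialityReport(z_wt=z_wt)
    gene_list = genes if genes is not None else sorted(work.genes)
    for gene in gene_list:
        disabled = reactions_disabled_by(work, {gene})
        if not disabled:
            z_ko = z_wt
        else:
            lb = lp.lb.copy()
            ub = lp.ub.copy()
            for rid in disabled:
                j = lp.col_of[rid]
                lb[j] = ub[j] = 0.0
            status, z, _ = lp.solve(c, sense="max", lb=lb, ub=ub)
            z_ko = z if status == "optimal" and z is not None else 0.0
        z_ko = min(max(z_ko, 0.0), z_wt)  # clip LP round-off outside [0, Z_wt]
        ratio = z_ko / z_wt
        report.results[gene] = GeneResult(
            gene=gene, z_wt=z_wt, z_ko=z_ko, ratio=ratio,
            label=classify(ratio, eps_zero, eps_full),
        )
    return report
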