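"""End-to-end analysis pipeline.

Runs the full workflow on one model from a single YAML config: census →
curation → FBA → (optional) minimal-medium search → substrate screen →
single-gene essentiality → FVA-based knockout ranking.  Every stage
writes a plain-text report (TSV/JSON/YAML) into the output directory and
the run log records versions, thresholds and the seed, so re-running an
identical config reproduces byte-identical reports.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .curation import check_model_balance, find_deadends, find_redundant
from .deletion import EPS_FULL, EPS_ZERO, single_gene_deletion
from .fba import apply_medium, solve_fba
from .fva import rank_knockouts
from .io import read_medium, read_sbml, read_tabular, write_medium
from .media import (
    DEFAULT_GROWTH_THRESHOLD,
    determine_minimal_media,
    screen_substrates,
    compare_predictions,
)
from .model import MetabolicModel, census, connectivity

ALL_STAGES = ("census", "curation", "fba", "minimal_media", "screen",
              "essentiality", "fva_ranking")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    model_path: str
    out_dir: str = "fluxkit_out"
    model_format: str = "auto"  # "sbml" | "tabular" | "auto"
    metabolites_path: str | None = None  # for tabular models
    medium_path: str | None = None
    objective: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    carbon_exchange: str | None = None
    candidate_exchanges: list[str] = field(default_factory=list)
    free_exchanges: list[str] = field(default_factory=list)
    substrates: list[str] = field(default_factory=list)
    observed: dict[str, bool] = field(default_factory=dict)
    uptake_bound: float = 20.0
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD
    eps_zero: float = EPS_ZERO
    eps_full: float = EPS_FULL
    gamma: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        if not Path(self.model_path).exists():
            raise FileNotFoundError(f"model file not found: {self.model_path}")
        if self.medium_path and not Path(self.medium_path).exists():
            raise FileNotFoundError(f"medium file not found: {self.medium_path}")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; known: {ALL_STAGES}")
        for name in ("growth_threshold", "eps_zero", "eps_full"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def load_model(config: PipelineConfig) -> MetabolicModel:
    fmt = config.model_format
    if fmt == "auto":
        fmt = "sbml" if config.model_path.endswith((".xml", ".sbml")) else "tabular"
    if fmt == "sbml":
        model = read_sbml(config.model_path)
    else:
        if not config.metabolites_path:
            raise ValueError("tabular models need metabolites_path")
        model = read_tabular(config.model_path, config.metabolites_path)
    if config.objective:
        model.objective_coefficients = {config.objective: 1.0}
        if model.biomass_reaction_id is None:
            model.biomass_reaction_id = config.objective
    return model


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {stage: output path or data}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(config)
    medium = read_medium(config.medium_path) if config.medium_path else None
    bundle: dict = {}
    log: dict = {
        "fluxkit_version": __version__,
        "python": sys.version.split()[0],
        "model": config.model_path,
        "seed": config.seed,
        "thresholds": {
            "growth_threshold": config.growth_threshold,
            "eps_zero": config.eps_zero,
            "eps_full": config.eps_full,
            "gamma": config.gamma,
        },
        "stages_run": [],
    }

    def stage(name):
        return name in config.stages

    try:
        if stage("census"):
            c = census(model)
            rows = [(k, v) for k, v in c.as_dict().items()
                    if not isinstance(v, dict)]
            rows += [
                (f"metabolites[{k}]", v)
                for k, v in sorted(c.metabolites_per_compartment.items())
            ]
            rows += [
                (f"reactions[{k}]", v)
                for k, v in sorted(c.reactions_per_compartment.items())
            ]
            pd.DataFrame(rows, columns=["feature", "count"]).to_csv(
                out / "census.tsv", sep="\t", index=False
            )
            bundle["census"] = c
            log["stages_run"].append("census")

        if stage("curation"):
            dd = find_deadends(model)
            pd.DataFrame(
                sorted((m, lab) for m, lab in dd.labels.items()),
                columns=["metabolite", "label"],
            ).to_csv(out / "deadends.tsv", sep="\t", index=False)
            red = find_redundant(model)
            bal = check_model_balance(model)
            with open(out / "curation.json", "w") as fh:
                json.dump(
                    {
                        "n_deadends": len(dd.deadends),
                        "deadends": dd.deadends,
                        "deadend_reactions": dd.deadend_reactions,
                        "duplicate_groups": red.duplicate_groups,
                        "isolated": red.isolated,
                        "n_unbalanced": sum(
                            e.status == "unbalanced" for e in bal.entries.values()
                        ),
                    },
                    fh, indent=2, sort_keys=True,
                )
            bundle["curation"] = {"deadends": dd, "redundancy": red, "balance": bal}
            log["stages_run"].append("curation")

        if stage("fba"):
            work = apply_medium(model, medium) if medium else model
            res = solve_fba(work)
            payload = {"status": res.status}
            if res.optimal:
                payload["objective_value"] = float(_fmt(res.objective_value))
                payload["nonzero_fluxes"] = {
                    rid: float(_fmt(v))
                    for rid, v in sorted(res.fluxes.items())
                    if abs(v) > 1e-6
                }
            with open(out / "fba.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            bundle["fba"] = res
            log["stages_run"].append("fba")

        if stage("minimal_media") and config.carbon_exchange:
            mm = determine_minimal_media(
                model, config.carbon_exchange,
                config.candidate_exchanges
                or [r.id for r in model.reactions if r.category == "exchange"],
                growth_threshold=config.growth_threshold,
                carbon_lb=-abs(config.uptake_bound),
                free_exchanges=config.free_exchanges,
            )
            write_medium(mm, out / "medium.yaml")
            bundle["minimal_media"] = mm
            log["stages_run"].append("minimal_media")

        if stage("screen") and config.substrates:
            base = bundle.get("minimal_media") or medium or {}
            screen = screen_substrates(
                model, base, config.substrates,
                uptake_bound=config.uptake_bound,
                growth_threshold=config.growth_threshold,
                observed=config.observed or None,
            )
            df = pd.DataFrame(
                [
                    {
                        "substrate": c.substrate,
                        "growth": _fmt(c.growth),
                        "predicted": "+" if c.predicted else "-",
                        "observed": (
                            "" if c.observed is None
                            else ("+" if c.observed else "-")
                        ),
                        "class": c.agreement_class or "",
                    }
                    for c in screen.calls
                ]
            )
            df.to_csv(out / "screen.tsv", sep="\t", index=False)
            bundle["screen"] = screen
            if config.observed:
                bundle["screen_comparison"] = compare_predictions(screen)
            log["stages_run"].append("screen")

        if stage("essentiality"):
            rep = single_gene_deletion(
                model, medium, eps_zero=config.eps_zero,
                eps_full=config.eps_full,
            )
            pd.DataFrame(
                [
                    {
                        "gene": g, "z_wt": _fmt(r.z_wt), "z_ko": _fmt(r.z_ko),
                        "ratio": _fmt(r.ratio), "label": r.label,
                    }
                    for g, r in sorted(rep.results.items())
                ]
            ).to_csv(out / "essentiality.tsv", sep="\t", index=False)
            bundle["essentiality"] = rep
            log["stages_run"].append("essentiality")

        if stage("fva_ranking"):
            rep = bundle.get("essentiality")
            genes = rep.genes_with_label("non_essential") + \
                rep.genes_with_label("partially_essential") if rep else None
            scores = rank_knockouts(model, medium, genes=genes,
                                    gamma=config.gamma)
            pd.DataFrame(
                [
                    {
                        "gene": s.gene,
                        "sd": "" if s.sd is None else _fmt(s.sd),
                        "n_used": s.n_used,
                        "status": s.status,
                        "group1_pairs": ";".join(f"{r}:{g}" for r, g in s.group1),
                        "group2_pairs": ";".join(f"{r}:{g}" for r, g in s.group2),
                    }
                    for s in scores
                ]
            ).to_csv(out / "sd.tsv", sep="\t", index=False)
            bundle["fva_ranking"] = scores
            log["stages_run"].append("fva_ranking")
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        done = set(log["stages_run"])
        pending = [s for s in config.stages if s not in done]
        stage_name = pending[0] if pending else "unknown"
        with open(out / "run_log.json", "w") as fh:
            json.dump({**log, "error": str(exc), "failed_stage": stage_name},
                      fh, indent=2, sort_keys=True)
        raise PipelineError(stage_name, str(exc)) from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    bundle["log"] = log
    return bundle
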