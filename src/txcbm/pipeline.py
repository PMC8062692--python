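"""Workflow orchestration: validated run configs, the full study pipeline, manifests.

``run_pipeline`` executes every (method, threshold) cell over one model and one
expression table: solve, activity-call, score against expression (confusion +
rank SSD), intersect active sets across methods, and, when evidence layers are
given, verify against multi-omics data.  Every artifact is a TSV/JSON file in
the configured output directory, and the manifest records the exact config so
each number is reproducible from manifest + inputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .evaluation import (
    OmicsEvidence,
    activity_from_expression,
    activity_from_flux,
    confusion,
    core_overlap,
    evaluated_reactions,
    multiomics_counts,
    multiomics_verify,
    ssd_for,
)
from .fba_engine import ZERO_FLUX_TOL, fba
from .integration import HpcofConfig, eflux, gimme, hpcof
from .model_core import load_model
from .transcriptome import load_fpkm, reaction_expression

logger = logging.getLogger("txcbm")

KNOWN_METHODS = ("fba", "gimme", "eflux", "hpcof")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    model_path: str
    expression_paths: list[str]
    out_dir: str
    model_format: str = "tabular_json"
    methods: list[str] = field(default_factory=lambda: list(KNOWN_METHODS))
    thresholds: list[float] = field(default_factory=lambda: [50.0])
    growth: float | None = None
    uptake: float | None = None
    flux_tolerance: float = ZERO_FLUX_TOL
    seed: int = 0
    evidence_paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


_DEFAULTS = {
    "model_format": "tabular_json",
    "methods": list(KNOWN_METHODS),
    "thresholds": [50.0],
    "growth": None,
    "uptake": None,
    "flux_tolerance": ZERO_FLUX_TOL,
    "seed": 0,
    "evidence_paths": {},
}
_REQUIRED = ("model_path", "expression_paths", "out_dir")


def validate_config(source) -> RunConfig:
    """Schema-check a config (path to JSON/YAML, or a dict); unknown keys fail."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise ConfigError(f"cannot read config from {type(source).__name__}")

    unknown = set(raw) - set(_REQUIRED) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    merged = {**_DEFAULTS, **raw}
    cfg = RunConfig(**merged)
    if cfg.flux_tolerance <= 0:
        raise ConfigError(f"flux_tolerance must be positive, got {cfg.flux_tolerance}")
    bad = [m for m in cfg.methods if m not in KNOWN_METHODS]
    if bad:
        raise ConfigError(f"unknown methods: {bad}")
    for t in cfg.thresholds:
        if not 0 < t < 100:
            raise ConfigError(f"threshold percentile {t} outside (0, 100)")
    if not cfg.expression_paths:
        raise ConfigError("expression_paths is empty")
    for p in [cfg.model_path, *cfg.expression_paths, *cfg.evidence_paths.values()]:
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    return cfg


def _solve_cell(model, rxn_expr, method: str, threshold: float, cfg: RunConfig):
    fixed = {}
    if cfg.uptake is not None and model.substrate_uptake_id is not None:
        fixed[model.substrate_uptake_id] = cfg.uptake
    if method == "fba":
        dist = fba(model, fixed=fixed)
        if not dist.optimal:
            raise RuntimeError(f"FBA {dist.status}")
        return dist, None
    if method == "gimme":
        res = gimme(model, rxn_expr, threshold_percentile=threshold,
                    growth=cfg.growth, uptake=cfg.uptake)
        return res.fluxes, res
    if method == "eflux":
        res = eflux(model, rxn_expr, uptake=cfg.uptake)
        return res.fluxes, res
    if method == "hpcof":
        res = hpcof(model, rxn_expr, config=HpcofConfig(), uptake=cfg.uptake)
        return res.fluxes, res
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every (method, threshold) cell and write the report bundle.

    Returns a summary dict mirroring the files written to ``cfg.out_dir``:
    per-cell confusion indices and SSD, the cross-method core-overlap
    partition, and multi-omics verification counts when evidence was supplied.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = load_model(cfg.model_path, format=cfg.model_format)
    expr = load_fpkm(cfg.expression_paths[0])
    for extra in cfg.expression_paths[1:]:
        logger.info("additional expression dataset (consensus use): %s", extra)
    rxn_expr = reaction_expression(model, expr)
    universe = [r for r in evaluated_reactions(model) if rxn_expr.has_genes.get(r)]

    rows = []
    flux_calls = {}
    stage = "setup"
    try:
        for method in cfg.methods:
            thresholds = cfg.thresholds if method == "gimme" else [cfg.thresholds[0]]
            for thr in thresholds:
                stage = f"{method}@P{thr:g}"
                dist, res = _solve_cell(model, rxn_expr, method, thr, cfg)
                label = f"{method}_p{thr:g}" if method == "gimme" else method
                dist.to_frame().to_csv(out / f"fluxes_{label}.tsv", sep="\t")
                call = activity_from_flux(dist, tol=cfg.flux_tolerance, subset=universe)
                flux_calls[label] = call
                sres = ssd_for(model, dist, rxn_expr, subset=universe)
                for eval_thr in (25.0, 50.0, 75.0):
                    truth_call = activity_from_expression(
                        rxn_expr, eval_thr, subset=universe
                    )
                    cm = confusion(call, truth_call)
                    rows.append(
                        {
                            "method": label,
                            "expression_threshold": eval_thr,
                            "biomass_flux": dist.biomass_flux,
                            "objective": dist.objective_value,
                            "ssd": sres.total,
                            "recovered": len(res.recovered_reactions) if res else 0,
                            **cm.as_dict(),
                        }
                    )
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    report = pd.DataFrame(rows)
    report.to_csv(out / "consistency_report.tsv", sep="\t", index=False)

    summary: dict = {"cells": rows}
    if len(flux_calls) >= 2:
        partition = core_overlap(flux_calls)
        partition_counts = {k: len(v) for k, v in partition.items()}
        (out / "core_overlap.json").write_text(
            json.dumps({k: sorted(v) for k, v in partition.items()}, indent=1)
        )
        summary["core_overlap"] = partition_counts

    if cfg.evidence_paths:
        def read_ids(path):
            return {
                line.strip() for line in Path(path).read_text().splitlines() if line.strip()
            }

        evidence = OmicsEvidence(
            transcript_genes=read_ids(cfg.evidence_paths.get("transcript", ""))
            if "transcript" in cfg.evidence_paths else set(),
            protein_genes=read_ids(cfg.evidence_paths.get("protein", ""))
            if "protein" in cfg.evidence_paths else set(),
            metabolites=read_ids(cfg.evidence_paths.get("metabolite", ""))
            if "metabolite" in cfg.evidence_paths else set(),
        )
        omics = {}
        for label, call in flux_calls.items():
            table = multiomics_verify(model, call, evidence)
            table.to_csv(out / f"multiomics_{label}.tsv", sep="\t")
            omics[label] = multiomics_counts(table)
        summary["multiomics"] = omics

    manifest = {
        "txcbm_version": __version__,
        "config": cfg.to_dict(),
        "n_evaluated_reactions": len(universe),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    summary["manifest"] = manifest
    return summary
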