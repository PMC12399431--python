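"""End-to-end orchestration: context model -> reference flux -> transformation
-> knockdown screen -> reports.

Every stage writes TSV artifacts whose comment headers record the config
hash, model hash and seed, so a rerun with identical inputs is
byte-identical (timestamps are deliberately not written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .config import RunConfig, SamplingConfig, Thresholds
from .context import FeasibilityGuard, select_inactive_genes, prune_model
from .exceptions import ConfigurationError
from .io import (
    config_hash,
    model_hash,
    read_differential,
    read_expression,
    read_pathways,
    write_table,
)
from .model_core import load_model, save_model
from .reference import ReferenceConfig, compute_reference
from .scoring import ScreenConfig, screen_and_score
from .transform import (
    apply_drug_constraint,
    build_problem,
    flux_fold_changes,
    pathway_flux_summary,
    solve_qm2ta,
)

log = logging.getLogger("qm2ta")

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - python < 3.11
    import tomli as tomllib


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a declarative TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    paths = raw.get("paths", {})
    cfg = RunConfig(
        model_path=paths.get("model", ""),
        expression_path=paths.get("expression", ""),
        de_path=paths.get("de", ""),
        metabolite_path=paths.get("metabolites", ""),
        pathway_path=paths.get("pathways"),
        treatment=raw.get("conditions", {}).get("treatment", ""),
        control=raw.get("conditions", {}).get("control", ""),
        thresholds=Thresholds(**raw.get("thresholds", {})),
        sampling=SamplingConfig(**raw.get("sampling", {})),
        drug_constraints=[
            (d["reaction"], float(d.get("fraction", 0.5)))
            for d in raw.get("drug_constraints", [])
        ],
        required_metabolites=list(raw.get("required_metabolites", [])),
    )
    if cfg.sampling.seed is None:
        raise ConfigurationError("sampling.seed is required for reproducibility")
    for label, p in [
        ("model", cfg.model_path),
        ("expression", cfg.expression_path),
        ("de", cfg.de_path),
    ]:
        if not p or not Path(p).exists():
            raise ConfigurationError(f"paths.{label} missing or unreadable: {p!r}")
    return cfg


def _headers(cfg_digest: str, mdl_digest: str, seed: int) -> list[str]:
    return [f"config_hash={cfg_digest}", f"model_hash={mdl_digest}", f"seed={seed}"]


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    digest = config_hash(dataclasses.asdict(config))
    thr = config.thresholds

    model = load_model(config.model_path)
    mdl_digest = model_hash(model)
    seed = int(config.sampling.seed)
    headers = _headers(digest, mdl_digest, seed)
    expr = read_expression(config.expression_path)
    de = read_differential(config.de_path, default_kind="gene")
    met = (
        read_differential(config.metabolite_path, default_kind="metabolite")
        if config.metabolite_path and Path(config.metabolite_path).exists()
        else None
    )

    # stage 1: condition-specific model
    guard = FeasibilityGuard(
        biomass_fraction=thr.biomass_guard,
        required_metabolites=tuple(config.required_metabolites),
        min_sink_flux=thr.min_sink_flux,
    )
    inactive = select_inactive_genes(expr, thr.fpkm)
    order = expr.max(axis=1).to_dict()
    context, removed, retained = prune_model(model, inactive, guard, order_key=order)
    save_model(context, outdir / "context_model.json")
    log.info(
        "build-context: %d candidates, %d removed, %d retained (%.1fs)",
        len(inactive), len(removed), len(retained), time.time() - t0,
    )

    # stage 2: reference flux
    ref_cfg = ReferenceConfig(
        biomass_fraction=thr.biomass_fraction,
        fva_fraction=thr.fva_fraction,
        n_samples=config.sampling.n_samples,
        thinning=config.sampling.thinning,
        seed=seed,
    )
    control_expr = expr[config.control].to_dict() if config.control in expr else expr.mean(axis=1).to_dict()
    required_sinks = [
        m for m in (met["measure_id"] if met is not None else [])
        if m in context.metabolites
    ] + [m for m in config.required_metabolites if m in context.metabolites]
    v_ref, _ = compute_reference(
        context, control_expr, ref_cfg,
        required_sinks=sorted(set(required_sinks)),
        min_sink_flux=thr.min_sink_flux,
    )
    v_ref.to_tsv(outdir / "reference_flux.tsv", header_lines=headers)
    log.info("reference-flux: %d reactions (%.1fs)", len(v_ref), time.time() - t0)

    # stage 3: transformation with drug constraints
    problem = build_problem(context, v_ref, de, met, p_th=thr.p_th)
    for rxn_id, fraction in config.drug_constraints:
        problem = apply_drug_constraint(problem, rxn_id, fraction)
    result = solve_qm2ta(problem)
    result.v_res.to_tsv(outdir / "transformed_flux.tsv", header_lines=headers)
    residuals = pd.DataFrame(
        sorted(result.residuals.items()), columns=["measure_id", "residual"]
    )
    write_table(residuals, outdir / "residuals.tsv", headers, index=False)
    fc_table, counts = flux_fold_changes(
        result.v_res, problem.v_ref, thr.fc_up, thr.fc_down
    )
    write_table(fc_table, outdir / "flux_fold_changes.tsv", headers)
    log.info(
        "transform: objective %.4g; categories %s (%.1fs)",
        result.objective, counts, time.time() - t0,
    )

    if config.pathway_path and Path(config.pathway_path).exists():
        pathway_map = read_pathways(config.pathway_path)
        summary = pathway_flux_summary(result.v_res, problem.v_ref, pathway_map)
        write_table(summary.to_frame(), outdir / "pathway_summary.tsv", headers)
    elif config.pathway_path:
        log.warning("pathway file %s missing; pathway report skipped",
                    config.pathway_path)

    # stage 4: knockdown screen
    screen_cfg = ScreenConfig(kd_fraction=thr.kd_fraction)
    table, _ = screen_and_score(problem, screen_cfg)
    write_table(table, outdir / "target_scores.tsv", headers, index=False)
    log.info("screen-targets: %d genes (%.1fs)", len(table), time.time() - t0)

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            dict(config_hash=digest, model_hash=mdl_digest, seed=seed,
                 objective=result.objective, categories=counts,
                 removed_genes=removed, retained_genes=retained),
            fh, indent=2, sort_keys=True,
        )
    return outdir
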