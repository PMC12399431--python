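"""Condition-specific model extraction by expression pruning.

Enzymes expressed below an FPKM floor are candidates for removal; a
candidate is actually removed only when the pruned model still (a) reaches
a set fraction of the original biomass optimum and (b) can synthesize or
take up every required metabolite (checked through per-metabolite sinks).
Removal is sequential and deterministic: candidates are visited in
ascending order of their maximum FPKM across conditions (ties broken
lexicographically), and the guard is re-checked after each removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import pandas as pd

from .config import DEFAULT_THRESHOLDS
from .exceptions import ConfigurationError, DomainError, ModelLookupError
from .model_core import add_sink, fba, gpr_is_active


@dataclass
class FeasibilityGuard:
    """Viability conditions a pruned model must keep satisfying."""

    biomass_fraction: float = DEFAULT_THRESHOLDS.biomass_guard
    required_metabolites: tuple[str, ...] = ()
    min_sink_flux: float = DEFAULT_THRESHOLDS.min_sink_flux

    def __post_init__(self) -> None:
        if not 0 < self.biomass_fraction <= 1:
            raise DomainError(
                f"biomass_fraction must lie in (0,1], got {self.biomass_fraction}"
            )


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Expression matrix: genes x conditions, FPKM >= 0 (NaN = missing)."""
    if expr.empty:
        raise DomainError("empty expression matrix")
    if (expr.fillna(0) < 0).any().any():
        raise DomainError("negative FPKM values in expression matrix")
    return expr


def select_inactive_genes(expr: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with FPKM below ``threshold`` in *every* condition.

    Missing entries never cause selection (they count as >= threshold).
    """
    validate_expression(expr)
    if threshold <= 0:
        return set()
    below = expr.fillna(threshold) < threshold
    return set(expr.index[below.all(axis=1)])


def _closed_reactions(model: cobra.Model, removed_genes: set[str]) -> set[str]:
    """Reactions whose GPR evaluates inactive with ``removed_genes`` out."""
    closed: set[str] = set()
    for g in removed_genes:
        if g not in model.genes:
            continue
        for rxn in model.genes.get_by_id(g).reactions:
            if rxn.gene_reaction_rule and not gpr_is_active(rxn.gpr, removed_genes):
                closed.add(rxn.id)
    return closed


def guard_satisfied(
    model: cobra.Model, baseline_optimum: float, guard: FeasibilityGuard,
    slack: float = 1e-9,
) -> bool:
    """Re-solve the model and check biomass and sink feasibility."""
    try:
        _, opt = fba(model)
    except Exception:
        return False
    if opt < guard.biomass_fraction * baseline_optimum - slack:
        return False
    for met in guard.required_metabolites:
        probe = model.copy()
        try:
            sid = add_sink(probe, met)
        except ModelLookupError:
            return False
        try:
            _, sflux = fba(probe, objective=sid, sense="max")
        except Exception:
            return False
        if sflux < guard.min_sink_flux - slack:
            return False
    return True


def prune_model(
    model: cobra.Model,
    candidate_genes: set[str],
    guard: FeasibilityGuard,
    order_key: dict[str, float] | None = None,
) -> tuple[cobra.Model, list[str], list[str]]:
    """Greedily remove candidate genes while the feasibility guard holds.

    Returns ``(pruned_model, removed, retained)``. ``order_key`` (e.g. the
    gene's maximum FPKM) fixes the visiting order; omitted keys sort first
    by gene id. The input model is not mutated; removed genes close the
    reactions whose GPR turns inactive (bounds set to 0), isozymes protect
    shared reactions.
    """
    base = model.copy()
    _, baseline = fba(base)
    if baseline <= 1e-9:
        raise ConfigurationError(
            "model produces no biomass; a fraction-of-optimum guard is vacuous"
        )
    if not guard_satisfied(base, baseline, guard):
        raise ConfigurationError(
            "feasibility guard is violated before any pruning; "
            "check biomass_fraction and required metabolites"
        )
    key = order_key or {}
    order = sorted(candidate_genes, key=lambda g: (key.get(g, 0.0), g))

    removed: list[str] = []
    retained: list[str] = []
    pruned = base
    closed_now: set[str] = set()
    original_bounds = {r.id: (r.lower_bound, r.upper_bound) for r in base.reactions}

    for gene in order:
        trial_removed = set(removed) | {gene}
        trial_closed = _closed_reactions(base, trial_removed)
        trial = pruned.copy()
        for rid in trial_closed - closed_now:
            trial.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        for rid in closed_now - trial_closed:  # cannot happen, defensive
            trial.reactions.get_by_id(rid).bounds = original_bounds[rid]
        if guard_satisfied(trial, baseline, guard):
            pruned = trial
            removed.append(gene)
            closed_now = trial_closed
        else:
            retained.append(gene)
    return pruned, removed, retained


def treatment_specific_pruning(
    base_model: cobra.Model,
    expr: pd.DataFrame,
    de_table: pd.DataFrame,
    treatment: str,
    control: str,
    guard: FeasibilityGuard,
    fpkm_threshold: float = DEFAULT_THRESHOLDS.fpkm,
    p_cut: float = DEFAULT_THRESHOLDS.de_p,
) -> cobra.Model:
    """Prune genes silenced by the treatment but active in the control.

    A gene qualifies when FPKM(treatment) < threshold, FPKM(control) >=
    threshold, and its differential-expression FDR-adjusted p < ``p_cut``;
    removal still passes through the feasibility guard.
    """
    validate_expression(expr)
    for cond in (treatment, control):
        if cond not in expr.columns:
            raise ModelLookupError(f"unknown condition: {cond}")
    padj = (
        de_table.loc[de_table["kind"] == "gene"]
        .set_index("measure_id")["p_adj"]
        .to_dict()
    )
    t = expr[treatment]
    c = expr[control]
    candidates = {
        g
        for g in expr.index
        if t.get(g, fpkm_threshold) < fpkm_threshold
        and c.get(g, 0.0) >= fpkm_threshold
        and padj.get(g, 1.0) < p_cut
        and not pd.isna(t.get(g))
    }
    order = expr.max(axis=1).to_dict()
    pruned, _, _ = prune_model(base_model, candidates, guard, order_key=order)
    return pruned
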