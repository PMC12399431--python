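"""The quadratic multiomic transformation (qM2TA) optimization.

Differentially expressed genes and differentially abundant metabolites
(jointly "measures") define per-reaction target fluxes v_ref * FC; the QP
finds the feasible flux state closest to all targets, each deviation
normalized by its expected excursion and weighted by the measure's
statistical significance, while unmeasured reactions are softly anchored
at the reference:

    min  sum_{m in DExp} W_m sum_{i in R_m} ((v_ref_i FC_m - v_i) / d1_im)^2
       + sum_{i in Ru} ((v_ref_i - v_i) / d2_i)^2
    s.t. S v = 0,  lb <= v <= ub,  drug constraints

with d1_im = max(|v_ref_i (FC_m - 1)|, eps), d2_i = max(|v_ref_i|, eps),
and W_m = log10(p_th) - log10(p_m) for p_m below the significance gate
p_th (0.25 FDR-adjusted), 0 otherwise. The absolute-value denominators
with an eps floor keep the objective a positive-definite separable
quadratic, and make it invariant to a common rescaling of v_ref and the
bounds. Genes map to reactions through the model's gene-reaction rules;
metabolites map to an irreversible sink consuming them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
import cobra
import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS
from .exceptions import DomainError, ModelLookupError
from .model_core import (
    FluxVector,
    add_sink,
    genes_to_reactions,
    model_bounds,
    stoichiometric_matrix,
)
from .qp import DiagQP, solve_diag_qp


def compute_weight(p_m: float, p_th: float = DEFAULT_THRESHOLDS.p_th) -> float:
    """Significance weight W_m = log10(p_th) - log10(p_m), floored at 0.

    Measures at or above the significance gate get zero weight and drop
    out of the objective.
    """
    if not 0 < p_m <= 1:
        raise DomainError(f"p-value must lie in (0,1], got {p_m}")
    if not 0 < p_th < 1:
        raise DomainError(f"p_th must lie in (0,1), got {p_th}")
    if p_m >= p_th:
        return 0.0
    return math.log10(p_th) - math.log10(p_m)


@dataclass(frozen=True)
class OmicsMeasure:
    """One differentially expressed gene or differentially abundant
    metabolite mapped onto the flux space."""

    id: str
    kind: str                     # "gene" | "metabolite"
    fc: float
    p: float
    weight: float
    reactions: frozenset[str]

    @property
    def sign(self) -> int:
        """Sign of log(FC): +1 up-regulated, -1 down-regulated."""
        if self.fc == 1.0:
            raise DomainError(f"measure {self.id}: FC = 1 has no direction")
        return 1 if self.fc > 1.0 else -1


@dataclass
class TransformationProblem:
    """A fully mapped qM2TA instance ready for the QP solver."""

    model: cobra.Model
    v_ref: FluxVector
    measures: tuple[OmicsMeasure, ...]
    ru: tuple[str, ...]
    p_th: float = DEFAULT_THRESHOLDS.p_th
    epsilon: float | None = None   # denominator floor; default 1e-6 * mean|v_ref|
    drug_constraints: tuple[tuple[str, float], ...] = ()

    def effective_epsilon(self) -> float:
        if self.epsilon is not None:
            return self.epsilon
        scale = float(np.mean(np.abs(self.v_ref.values.values)))
        return 1e-6 * scale if scale > 0 else 1e-9


@dataclass
class TransformationResult:
    v_res: FluxVector
    objective: float
    residuals: dict[str, float]    # per-measure weighted squared deviation
    status: str = "optimal"


def map_measures(
    model: cobra.Model,
    de_table: pd.DataFrame,
    metabolite_table: pd.DataFrame | None = None,
    p_th: float = DEFAULT_THRESHOLDS.p_th,
) -> tuple[list[OmicsMeasure], list[str], int]:
    """Map omics tables onto reactions; returns (measures, Ru, n_dropped).

    Gene measures map through the gene-reaction rules; metabolite measures
    map to a sink consuming the metabolite (added to ``model`` in place if
    absent). Measures at p >= p_th, with FC = 1, mapping to no reaction,
    or naming an unknown metabolite are dropped (counted in ``n_dropped``).
    ``Ru`` is every model reaction not claimed by a surviving measure.
    """
    frames = [de_table.assign(kind=de_table.get("kind", "gene"))]
    if metabolite_table is not None and len(metabolite_table):
        frames.append(metabolite_table.assign(kind="metabolite"))
    table = pd.concat(frames, ignore_index=True)
    measures: list[OmicsMeasure] = []
    dropped = 0
    for row in table.itertuples(index=False):
        fc, p = float(row.fc), float(row.p_adj)
        if fc <= 0:
            raise DomainError(f"measure {row.measure_id}: fold change must be > 0")
        w = compute_weight(p, p_th)
        if w == 0.0:
            dropped += 1
            continue
        if fc == 1.0:
            warnings.warn(
                f"measure {row.measure_id}: FC = 1 carries no direction; dropped"
            )
            dropped += 1
            continue
        if row.kind == "gene":
            rxns = genes_to_reactions(model, row.measure_id)
            if not rxns:
                warnings.warn(
                    f"gene {row.measure_id} maps to no reaction in the model; dropped"
                )
                dropped += 1
                continue
        elif row.kind == "metabolite":
            try:
                rxns = {add_sink(model, row.measure_id)}
            except ModelLookupError:
                warnings.warn(
                    f"metabolite {row.measure_id} absent from the model; dropped"
                )
                dropped += 1
                continue
        else:
            raise DomainError(f"unknown measure kind: {row.kind!r}")
        measures.append(
            OmicsMeasure(str(row.measure_id), str(row.kind), fc, p, w, frozenset(rxns))
        )
    claimed = set().union(*(m.reactions for m in measures)) if measures else set()
    ru = [r.id for r in model.reactions if r.id not in claimed]
    return measures, ru, dropped


def build_problem(
    model: cobra.Model,
    v_ref: FluxVector,
    de_table: pd.DataFrame,
    metabolite_table: pd.DataFrame | None = None,
    p_th: float = DEFAULT_THRESHOLDS.p_th,
    epsilon: float | None = None,
) -> TransformationProblem:
    """Convenience constructor mapping tables onto a model copy."""
    model = model.copy()
    measures, ru, _ = map_measures(model, de_table, metabolite_table, p_th)
    v_ref = _extend_reference(model, v_ref)
    return TransformationProblem(
        model, v_ref, tuple(measures), tuple(ru), p_th, epsilon
    )


def _extend_reference(model: cobra.Model, v_ref: FluxVector) -> FluxVector:
    """Reindex v_ref on the model, zero-filling sinks added for measures."""
    ids = [r.id for r in model.reactions]
    values = v_ref.values.reindex(ids).fillna(0.0)
    return FluxVector(values, v_ref.label, dict(v_ref.provenance))


def apply_drug_constraint(
    problem: TransformationProblem, reaction_id: str, fraction: float
) -> TransformationProblem:
    """Cap a reaction's upper bound at fraction x its reference flux.

    Models a flux-limiting drug (e.g. a glutaminase inhibitor capping the
    glutaminase reaction at half the reference flux). Returns a new problem
    on a model copy.
    """
    if reaction_id not in problem.model.reactions:
        raise ModelLookupError(f"unknown reaction: {reaction_id}")
    model = problem.model.copy()
    rxn = model.reactions.get_by_id(reaction_id)
    new_ub = fraction * problem.v_ref[reaction_id]
    rxn.lower_bound = min(rxn.lower_bound, new_ub)
    rxn.upper_bound = new_ub
    return replace(
        problem,
        model=model,
        drug_constraints=problem.drug_constraints + ((reaction_id, fraction),),
    )


def _quadratic_coefficients(
    problem: TransformationProblem,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Assemble the separable objective sum a_i v_i^2 - 2 b_i v_i + const."""
    ids = [r.id for r in problem.model.reactions]
    index = {rid: k for k, rid in enumerate(ids)}
    vref = problem.v_ref.reindex_like(problem.model).values.values
    eps = problem.effective_epsilon()
    n = len(ids)
    a = np.zeros(n)
    b = np.zeros(n)
    const = 0.0
    for m in problem.measures:
        for rid in m.reactions:
            i = index[rid]
            target = vref[i] * m.fc
            d1 = max(abs(vref[i] * (m.fc - 1.0)), eps)
            c = m.weight / (d1 * d1)
            a[i] += c
            b[i] += c * target
            const += c * target * target
    ru_set = set(problem.ru)
    for rid in ru_set:
        i = index[rid]
        d2 = max(abs(vref[i]), eps)
        c = 1.0 / (d2 * d2)
        a[i] += c
        b[i] += c * vref[i]
        const += c * vref[i] * vref[i]
    return a, b, const


def evaluate_objective(problem: TransformationProblem, v: pd.Series) -> float:
    """The transformation objective evaluated at an arbitrary flux vector."""
    vref = problem.v_ref.reindex_like(problem.model).values
    eps = problem.effective_epsilon()
    total = 0.0
    for m in problem.measures:
        for rid in m.reactions:
            d1 = max(abs(vref[rid] * (m.fc - 1.0)), eps)
            total += m.weight * ((vref[rid] * m.fc - v[rid]) / d1) ** 2
    for rid in problem.ru:
        d2 = max(abs(vref[rid]), eps)
        total += ((vref[rid] - v[rid]) / d2) ** 2
    return float(total)


def solve_qm2ta(problem: TransformationProblem) -> TransformationResult:
    """Solve the transformation QP; certified convex (diagonal PSD Hessian).

    With no significant measures the optimum is the projection of v_ref
    onto the feasible set (and v_ref itself when feasible).
    """
    model = problem.model
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    a, b, const = _quadratic_coefficients(problem)
    v, obj = solve_diag_qp(DiagQP(S, a, b, lb, ub, const))
    ids = [r.id for r in model.reactions]
    series = pd.Series(v, index=ids)
    vref = problem.v_ref.reindex_like(model).values
    eps = problem.effective_epsilon()
    residuals = {}
    for m in problem.measures:
        r = 0.0
        for rid in m.reactions:
            d1 = max(abs(vref[rid] * (m.fc - 1.0)), eps)
            r += m.weight * ((vref[rid] * m.fc - series[rid]) / d1) ** 2
        residuals[m.id] = float(r)
    return TransformationResult(
        v_res=FluxVector(series, label="qm2ta"),
        objective=max(obj, 0.0),
        residuals=residuals,
    )


def flux_fold_changes(
    v_res: FluxVector,
    v_ref: FluxVector,
    up_threshold: float = DEFAULT_THRESHOLDS.fc_up,
    down_threshold: float = DEFAULT_THRESHOLDS.fc_down,
    epsilon: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-reaction |flux| fold changes and up/down/unchanged categories.

    FC = |v_res| / max(|v_ref|, eps); a reaction is "up" at FC >=
    ``up_threshold`` (a 25% or larger increase by default), "down" at FC <=
    ``down_threshold``, otherwise "unchanged".
    """
    if not (up_threshold >= 1.0 >= down_threshold > 0):
        raise DomainError("need up_threshold >= 1 >= down_threshold > 0")
    ref = v_ref.values
    res = v_res.values.reindex(ref.index)
    if res.isna().any():
        raise ModelLookupError("flux vectors cover different reaction sets")
    scale = float(np.mean(np.abs(ref.values)))
    eps = epsilon if epsilon is not None else (1e-6 * scale if scale > 0 else 1e-9)
    fc = res.abs() / np.maximum(ref.abs(), eps)
    fc[(ref.abs() < eps) & (res.abs() < eps)] = 1.0  # 0/0: no change, not "down"
    category = pd.Series("unchanged", index=ref.index)
    category[fc >= up_threshold] = "up"
    category[fc <= down_threshold] = "down"
    table = pd.DataFrame(
        {"v_ref": ref, "v_res": res, "fc": fc, "category": category}
    ).rename_axis("reaction_id")
    counts = {
        "up": int((category == "up").sum()),
        "down": int((category == "down").sum()),
        "unchanged": int((category == "unchanged").sum()),
    }
    return table, counts


def pathway_flux_summary(
    v_res: FluxVector,
    v_ref: FluxVector,
    pathway_map: dict[str, str],
) -> pd.Series:
    """log2 fold change of total |flux| per pathway relative to control.

    ``pathway_map`` assigns reactions to pathway labels (KEGG-style);
    unassigned reactions are ignored. Pathways with zero total reference
    flux are reported as NaN rather than +/- infinity.
    """
    if not pathway_map:
        raise DomainError("empty pathway map")
    ref = v_ref.values.abs()
    res = v_res.values.abs()
    rows = {}
    pathways = sorted(set(pathway_map.values()))
    for pw in pathways:
        rxns = [r for r, p in pathway_map.items() if p == pw and r in ref.index]
        if not rxns:
            continue
        tot_ref = float(ref[rxns].sum())
        tot_res = float(res[rxns].sum())
        if tot_ref > 0 and tot_res > 0:
            rows[pw] = math.log2(tot_res / tot_ref)
        else:
            rows[pw] = float("nan")  # undefined ratio, never +/- infinity
    return pd.Series(rows, name="log2_fc").rename_axis("pathway")
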