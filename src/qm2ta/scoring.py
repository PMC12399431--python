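"""Knockdown screening and target scoring.

A transformation score (TS) measures how far a flux state has moved in the
directions the omics measures call for:

    TS = sum_{m in DE} W_m sign(log FC_m) sum_{i in R_m} (|v_res_i| - |v_ref_i|)

Each candidate gene is evaluated twice: (a) re-running the transformation
QP with the gene's reactions capped at half their control flux (does the
knockdown impede the adaptation?), and (b) projecting the adapted state
with MOMA under the same cap anchored at the adapted flux (does the
knockdown revert the adapted state?). The two TS drops combine into the
final target score

    S_g = 1000 |Dif_qm2ta * Dif_moma| / TS_base^2 * min(sign Dif_qm2ta, sign Dif_moma)

which is positive exactly when both knockdown effects point the right way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS
from .exceptions import DomainError, InfeasibleError, NumericalError, ScoringError
from .model_core import (
    FluxVector,
    genes_to_reactions,
    knockdown_bounds,
    model_bounds,
    stoichiometric_matrix,
)
from .qp import DiagQP, solve_diag_qp
from .transform import OmicsMeasure, TransformationProblem, solve_qm2ta


@dataclass
class ScreenConfig:
    """Knockdown screen settings."""

    kd_fraction: float = DEFAULT_THRESHOLDS.kd_fraction  # 0.5
    candidate_genes: tuple[str, ...] | None = None  # None = all GPR genes

    def __post_init__(self) -> None:
        if not 0 <= self.kd_fraction < 1:
            raise DomainError("kd_fraction must lie in [0,1)")


@dataclass
class ScreenResult:
    scores: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)


def transformation_score(
    v_res: FluxVector,
    v_ref: FluxVector,
    measures: tuple[OmicsMeasure, ...] | list[OmicsMeasure],
) -> float:
    """Signed, significance-weighted agreement between a flux state's
    |flux| changes and the measured fold-change directions."""
    res = v_res.values.abs()
    ref = v_ref.values.abs()
    ts = 0.0
    for m in measures:
        s = m.sign  # raises DomainError for FC = 1
        inner = sum(float(res[rid] - ref[rid]) for rid in m.reactions)
        ts += m.weight * s * inner
    return ts


def moma(
    model: cobra.Model,
    v_anchor: FluxVector,
    kd: tuple[str, float, FluxVector] | None = None,
) -> FluxVector:
    """Minimization of metabolic adjustment.

    Finds the feasible flux nearest (least squares) to ``v_anchor``. When
    ``kd = (gene, fraction, anchor_for_bounds)`` is given, the gene's
    reactions are first capped at fraction x the bound-anchor flux. A
    feasible anchor with no knockdown is returned unchanged (the objective's
    zero).
    """
    if kd is not None:
        gene, fraction, bound_anchor = kd
        model = knockdown_bounds(model, gene, fraction, bound_anchor)
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    anchor = v_anchor.reindex_like(model).values.values
    qp = DiagQP(S, np.ones(len(lb)), anchor, lb, ub, const=float(anchor @ anchor))
    v, _ = solve_diag_qp(qp)
    ids = [r.id for r in model.reactions]
    return FluxVector(pd.Series(v, index=ids), label="moma")


def qm2ta_kd_screen(
    problem: TransformationProblem,
    config: ScreenConfig,
    v_res_base: FluxVector | None = None,
) -> ScreenResult:
    """Re-solve the transformation QP under each candidate knockdown.

    Knockdown bounds are anchored at the reference (control) flux. Genes
    whose knockdown makes the problem infeasible are flagged, not scored.
    """
    from .transform import _quadratic_coefficients

    genes = _candidates(problem.model, config)
    out = ScreenResult()
    if not genes:
        return out
    # the knockdown only moves bounds: assemble the objective once and
    # re-solve the same QP under per-gene bound edits
    model = problem.model
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    a, b, const = _quadratic_coefficients(problem)
    ids = [r.id for r in model.reactions]
    index = {rid: i for i, rid in enumerate(ids)}
    anchor = problem.v_ref.reindex_like(model).values.values
    for g in genes:
        idxs = [index[rid] for rid in sorted(genes_to_reactions(model, g))]
        kd_lb, kd_ub = _kd_bounds(lb, ub, idxs, anchor, config.kd_fraction)
        try:
            v, _ = solve_diag_qp(DiagQP(S, a, b, kd_lb, kd_ub, const))
        except (InfeasibleError, NumericalError):
            out.status[g] = "infeasible"
            continue
        v_res = FluxVector(pd.Series(v, index=ids), label="qm2ta")
        out.scores[g] = transformation_score(v_res, problem.v_ref, problem.measures)
        out.status[g] = "ok"
    return out


def moma_kd_screen(
    problem: TransformationProblem,
    v_res_base: FluxVector,
    config: ScreenConfig,
) -> ScreenResult:
    """MOMA from the adapted state under each candidate knockdown.

    Both the distance anchor and the knockdown bounds use the adapted flux
    v_res_base: the screen asks whether halving the gene's adapted flux
    drags the state back toward the control.
    """
    genes = _candidates(problem.model, config)
    out = ScreenResult()
    if not genes:
        return out
    model = problem.model
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    ids = [r.id for r in model.reactions]
    index = {rid: i for i, rid in enumerate(ids)}
    anchor = v_res_base.reindex_like(model).values.values
    ones = np.ones(len(ids))
    const = float(anchor @ anchor)
    for g in genes:
        idxs = [index[rid] for rid in sorted(genes_to_reactions(model, g))]
        kd_lb, kd_ub = _kd_bounds(lb, ub, idxs, anchor, config.kd_fraction)
        try:
            v, _ = solve_diag_qp(DiagQP(S, ones, anchor, kd_lb, kd_ub, const))
        except (InfeasibleError, NumericalError):
            out.status[g] = "infeasible"
            continue
        fv = FluxVector(pd.Series(v, index=ids), label="moma")
        out.scores[g] = transformation_score(fv, problem.v_ref, problem.measures)
        out.status[g] = "ok"
    return out


def _kd_bounds(
    lb: np.ndarray,
    ub: np.ndarray,
    idxs: list[int],
    anchor: np.ndarray,
    fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Array form of :func:`qm2ta.model_core.knockdown_bounds`."""
    kd_lb, kd_ub = lb.copy(), ub.copy()
    for i in idxs:
        if anchor[i] >= 0:
            kd_ub[i] = min(kd_ub[i], fraction * anchor[i])
            kd_lb[i] = min(kd_lb[i], kd_ub[i])
        else:
            kd_lb[i] = max(kd_lb[i], fraction * anchor[i])
            kd_ub[i] = max(kd_ub[i], kd_lb[i])
    return kd_lb, kd_ub


def _candidates(model: cobra.Model, config: ScreenConfig) -> list[str]:
    if config.candidate_genes is not None:
        return sorted(config.candidate_genes)
    return sorted(g.id for g in model.genes)


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def score_targets(
    ts_base: float,
    qm2ta_screen: ScreenResult,
    moma_screen: ScreenResult,
) -> pd.DataFrame:
    """Combine the two knockdown screens into ranked target scores.

    Dif_qm2ta = TS_base - TS(qM2TA knockdown); Dif_moma = TS_base -
    TS(MOMA knockdown); S_g as in the module docstring. Ranked by S_g
    descending, ties broken lexicographically; genes infeasible in either
    screen carry status "infeasible" and no rank.
    """
    if ts_base == 0:
        raise ScoringError(
            "TS_base = 0: target-score normalization undefined; "
            "report raw TS differences instead"
        )
    genes = sorted(set(qm2ta_screen.status) | set(moma_screen.status))
    rows = []
    for g in genes:
        ok = (
            qm2ta_screen.status.get(g) == "ok"
            and moma_screen.status.get(g) == "ok"
        )
        if not ok:
            rows.append(
                dict(gene_id=g, ts_base=ts_base, ts_qm2ta_kd=np.nan,
                     ts_moma_kd=np.nan, dif_qm2ta=np.nan, dif_moma=np.nan,
                     s_g=np.nan, status="infeasible")
            )
            continue
        ts_q = qm2ta_screen.scores[g]
        ts_m = moma_screen.scores[g]
        dif_q = ts_base - ts_q
        dif_m = ts_base - ts_m
        s_g = (
            1000.0
            * abs(dif_q * dif_m)
            / (ts_base * ts_base)
            * min(_sign(dif_q), _sign(dif_m))
        )
        rows.append(
            dict(gene_id=g, ts_base=ts_base, ts_qm2ta_kd=ts_q, ts_moma_kd=ts_m,
                 dif_qm2ta=dif_q, dif_moma=dif_m, s_g=s_g, status="ok")
        )
    table = pd.DataFrame(rows)
    scored = table[table["status"] == "ok"].sort_values(
        ["s_g", "gene_id"], ascending=[False, True]
    )
    table["rank"] = np.nan
    table.loc[scored.index, "rank"] = np.arange(1, len(scored) + 1)
    return (
        table.sort_values(["rank"], na_position="last")
        .reset_index(drop=True)
    )


def screen_and_score(
    problem: TransformationProblem,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, FluxVector]:
    """End-to-end screen: base transformation, both knockdown screens,
    and the ranked target table. Returns (table, base adapted flux)."""
    config = config or ScreenConfig()
    base = solve_qm2ta(problem)
    ts_base = transformation_score(base.v_res, problem.v_ref, problem.measures)
    q = qm2ta_kd_screen(problem, config)
    m = moma_kd_screen(problem, base.v_res, config)
    return score_targets(ts_base, q, m), base.v_res
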