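"""Reference (control-condition) flux distribution.

The chain follows the published procedure: an expression-weighted flux
minimization (GIME3-style) pinned to a fraction of maximal biomass and to
production of every measured metabolite; flux variability analysis
restricted to near-optimal weighted flux; artificial-centering hit-and-run
sampling of the restricted polytope; and the componentwise sample mean as
the reference state v_ref.

Reaction weights are w_i = 1 / (1 + e_i), with e_i the GPR-aggregated FPKM
of reaction i: continuous, monotone-decreasing in expression, so poorly
expressed enzymes are penalized for carrying flux. Reactions without
expression evidence receive the median weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd
from cobra.sampling import ACHRSampler
from scipy.optimize import linprog

from .config import DEFAULT_THRESHOLDS
from .exceptions import DomainError, InfeasibleError, UnboundedError
from .model_core import (
    FluxVector,
    add_sink,
    biomass_reaction_id,
    evaluate_gpr,
    fba,
    model_bounds,
    stoichiometric_matrix,
)

WEIGHTED_FLUX_CONSTRAINT = "weighted_flux_budget"


@dataclass
class ReferenceConfig:
    """Parameters of the reference-flux chain."""

    biomass_fraction: float = DEFAULT_THRESHOLDS.biomass_fraction  # 0.95
    fva_fraction: float = DEFAULT_THRESHOLDS.fva_fraction          # 0.99
    n_samples: int = 1000
    thinning: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.biomass_fraction <= 1:
            raise DomainError("biomass_fraction must lie in (0,1]")
        if not 0 <= self.fva_fraction <= 1:
            raise DomainError("fva_fraction must lie in [0,1]")
        if self.n_samples < 1 or self.thinning < 1:
            raise DomainError("n_samples and thinning must be positive")


@dataclass
class FluxSamples:
    """n_samples x reactions flux matrix with sampling provenance."""

    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def mean(self) -> pd.Series:
        return self.samples.mean(axis=0)


def reaction_expression(
    model: cobra.Model, gene_fpkm: Mapping[str, float]
) -> dict[str, float | None]:
    """GPR-aggregated expression per reaction (None = no evidence)."""
    out: dict[str, float | None] = {}
    for rxn in model.reactions:
        if not rxn.gene_reaction_rule:
            out[rxn.id] = None
        else:
            out[rxn.id] = evaluate_gpr(rxn.gpr, gene_fpkm)
    return out


def gime3_weights(model: cobra.Model, gene_fpkm: Mapping[str, float]) -> np.ndarray:
    """w_i = 1 / (1 + e_i); unknown expression gets the median weight."""
    expr = reaction_expression(model, gene_fpkm)
    known = [1.0 / (1.0 + e) for e in expr.values() if e is not None]
    fallback = float(np.median(known)) if known else 1.0
    return np.array(
        [
            1.0 / (1.0 + expr[r.id]) if expr[r.id] is not None else fallback
            for r in model.reactions
        ]
    )


def prepare_reference_model(
    model: cobra.Model,
    biomass_fraction: float,
    required_sinks: Iterable[str] = (),
    min_sink_flux: float = DEFAULT_THRESHOLDS.min_sink_flux,
) -> tuple[cobra.Model, float]:
    """Copy of the model with biomass and metabolite-sink floors as bounds.

    Sinks are created (irreversible, export-positive) for each metabolite in
    ``required_sinks`` if absent and given a lower bound of
    ``min_sink_flux`` so the reference state produces every measured
    metabolite. Returns the constrained copy and the unconstrained biomass
    optimum.
    """
    constrained = model.copy()
    _, optimum = fba(constrained)
    for met in required_sinks:
        sid = add_sink(constrained, met)
        rxn = constrained.reactions.get_by_id(sid)
        rxn.lower_bound = max(rxn.lower_bound, min_sink_flux)
    bm = biomass_reaction_id(constrained)
    bm_rxn = constrained.reactions.get_by_id(bm)
    bm_rxn.lower_bound = max(bm_rxn.lower_bound, biomass_fraction * optimum)
    return constrained, optimum


def gime3_minimize(
    model: cobra.Model,
    gene_fpkm: Mapping[str, float],
    weights: np.ndarray | None = None,
) -> tuple[FluxVector, float]:
    """Expression-weighted flux minimization: min sum_i w_i |v_i|.

    ``model`` must already carry its biomass / sink floors as bounds (see
    :func:`prepare_reference_model`). |v| is handled exactly by splitting
    each flux into forward and reverse nonnegative parts.
    """
    if weights is None:
        weights = gime3_weights(model, gene_fpkm)
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    n = len(lb)
    # v = p - q with p, q >= 0; bounds chosen so p - q spans exactly [lb, ub]
    p_bounds = list(zip(np.maximum(lb, 0.0), np.maximum(ub, 0.0)))
    q_bounds = list(zip(np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)))
    A_eq = np.hstack([S, -S])
    c = np.concatenate([weights, weights])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=p_bounds + q_bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(
            "weighted flux minimization infeasible",
            hint="biomass floor or metabolite-sink floors cannot be met",
        )
    if res.status != 0:
        raise InfeasibleError(f"weighted flux minimization failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    fv = FluxVector(pd.Series(v, index=[r.id for r in model.reactions]))
    return fv, float(res.fun)


def restrict_to_fva(
    model: cobra.Model,
    weights: np.ndarray,
    objective_value: float,
    fva_fraction: float,
) -> cobra.Model:
    """Tighten bounds to the FVA ranges within a weighted-flux budget.

    For a minimization objective, "within fraction f of optimal" is read as
    sum_i w_i |v_i| <= optimum / f, which keeps the optimal face inside the
    restricted set; f = 0 disables the budget. The budget constraint stays
    attached to the returned model so downstream sampling honours it.
    """
    restricted = model.copy()
    if fva_fraction > 0 and np.isfinite(objective_value):
        budget = objective_value / fva_fraction
        expr = sum(
            w * (rxn.forward_variable + rxn.reverse_variable)
            for w, rxn in zip(weights, restricted.reactions)
        )
        constraint = restricted.problem.Constraint(
            expr, ub=budget, name=WEIGHTED_FLUX_CONSTRAINT
        )
        restricted.add_cons_vars([constraint])
    from cobra.flux_analysis import flux_variability_analysis

    ranges = flux_variability_analysis(
        restricted, fraction_of_optimum=0.0, processes=1
    )
    slack = 1e-9
    for rxn in restricted.reactions:
        lo = ranges.loc[rxn.id, "minimum"] - slack
        hi = ranges.loc[rxn.id, "maximum"] + slack
        rxn.bounds = (
            max(rxn.lower_bound, lo),
            min(rxn.upper_bound, max(hi, max(rxn.lower_bound, lo))),
        )
    return restricted


def achr_sample(
    model: cobra.Model,
    n_samples: int,
    thinning: int = 100,
    seed: int = 0,
) -> FluxSamples:
    """Artificial-centering hit-and-run samples of the flux polytope.

    Deterministic for a fixed seed. Raises :class:`UnboundedError` when the
    polytope has unbounded directions.
    """
    lb, ub = model_bounds(model)
    if np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub)):
        from cobra.flux_analysis import flux_variability_analysis

        open_ids = [
            r.id
            for r in model.reactions
            if not np.isfinite(r.lower_bound) or not np.isfinite(r.upper_bound)
        ]
        try:
            ranges = flux_variability_analysis(
                model, fraction_of_optimum=0.0, processes=1
            )
        except Exception as exc:
            raise UnboundedError(
                f"flux polytope unbounded (reactions with open bounds: "
                f"{open_ids[:5]}): {exc}",
                reactions=open_ids,
            ) from exc
        open_ids = [
            rid
            for rid in ranges.index
            if not np.isfinite(ranges.loc[rid, "minimum"])
            or not np.isfinite(ranges.loc[rid, "maximum"])
        ]
        if open_ids:
            raise UnboundedError(
                f"flux polytope unbounded along {open_ids[:5]}", reactions=open_ids
            )
    try:
        sampler = ACHRSampler(model, thinning=thinning, seed=seed)
        df = sampler.sample(n_samples)
    except Exception:
        # a 0-dimensional polytope (all fluxes pinned) has nothing to walk:
        # fall back to its unique point when FVA certifies full degeneracy
        from cobra.flux_analysis import flux_variability_analysis

        ranges = flux_variability_analysis(model, fraction_of_optimum=0.0, processes=1)
        width = (ranges["maximum"] - ranges["minimum"]).abs().max()
        if width > 1e-9:
            raise
        point = (ranges["maximum"] + ranges["minimum"]) / 2.0
        df = pd.DataFrame(
            np.tile(point.values, (n_samples, 1)), columns=ranges.index
        )[[r.id for r in model.reactions]]
    return FluxSamples(
        df,
        provenance=dict(seed=seed, thinning=thinning, n_samples=n_samples),
    )


def compute_reference(
    model: cobra.Model,
    gene_fpkm: Mapping[str, float],
    config: ReferenceConfig,
    required_sinks: Iterable[str] = (),
    min_sink_flux: float = DEFAULT_THRESHOLDS.min_sink_flux,
) -> tuple[FluxVector, cobra.Model]:
    """Full reference chain; returns (v_ref, restricted sampling model).

    The restricted model retains the biomass floor, sink floors and
    weighted-flux budget the samples were drawn under; because those
    constraints carve a convex set, their mean (the reference) satisfies
    them too.
    """
    constrained, optimum = prepare_reference_model(
        model, config.biomass_fraction, required_sinks, min_sink_flux
    )
    weights = gime3_weights(constrained, gene_fpkm)
    _, objective = gime3_minimize(constrained, gene_fpkm, weights)
    restricted = restrict_to_fva(constrained, weights, objective, config.fva_fraction)
    samples = achr_sample(restricted, config.n_samples, config.thinning, config.seed)
    ref = FluxVector(
        samples.mean(),
        label="reference",
        provenance=dict(
            seed=config.seed,
            n_samples=config.n_samples,
            thinning=config.thinning,
            biomass_fraction=config.biomass_fraction,
            fva_fraction=config.fva_fraction,
            gime3_objective=objective,
            biomass_optimum=optimum,
        ),
    )
    return ref, restricted
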