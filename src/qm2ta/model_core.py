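"""Constraint-based model plumbing: I/O, FBA/FVA, GPR evaluation, bound edits.

The in-memory model container is :class:`cobra.Model`; this module wraps the
COBRA toolchain behind a small functional surface and adds the conventions
the rest of the pipeline relies on:

* flux vectors are :class:`FluxVector` objects keyed by reaction id;
* exchange/sink reactions are written export-positive (``met ->``), so
  uptake is a negative flux;
* sink reactions added for measured metabolites are irreversible
  (``SK_<met>: met ->`` with bounds ``[0, large]``).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd
from cobra.core.gene import GPR
from cobra.util.array import create_stoichiometric_matrix

from .config import DEFAULT_TOL, Tolerances
from .exceptions import (
    ConfigurationError,
    DomainError,
    FormatError,
    InfeasibleError,
    ModelLookupError,
)

SINK_PREFIX = "SK_"
DEFAULT_SINK_BOUND = 1000.0


# ---------------------------------------------------------------------------
# Flux vectors
# ---------------------------------------------------------------------------

@dataclass
class FluxVector:
    """One flux value per reaction of a model.

    ``label`` records the role of the vector: ``reference`` (control
    condition), ``qm2ta`` (transformed state) or ``moma`` (knockdown
    projection).
    """

    values: pd.Series
    label: str = "reference"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.values[reaction_id])

    def __len__(self) -> int:
        return len(self.values)

    def reindex_like(self, model: cobra.Model) -> "FluxVector":
        ids = [r.id for r in model.reactions]
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ModelLookupError(
                f"flux vector is missing reactions: {sorted(missing)[:5]}"
            )
        return FluxVector(self.values.reindex(ids), self.label, dict(self.provenance))

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("reaction_id\tflux\n")
            for rid, v in self.values.items():
                fh.write(f"{rid}\t{v:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "reference") -> "FluxVector":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"reaction_id", "flux"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns reaction_id, flux")
        return cls(pd.Series(df["flux"].values, index=df["reaction_id"]), label)


def stoichiometric_matrix(model: cobra.Model) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions)."""
    return create_stoichiometric_matrix(model)


def model_bounds(model: cobra.Model) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


def check_flux(
    model: cobra.Model, flux: FluxVector, tol: Tolerances = DEFAULT_TOL,
    steady_state: float | None = None,
) -> None:
    """Assert a flux vector satisfies S v = 0 and the model bounds.

    Raises :class:`DomainError` on violation; used as an internal
    post-condition and in tests.
    """
    fv = flux.reindex_like(model)
    v = fv.values.values
    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    ss_tol = tol.steady_state if steady_state is None else steady_state
    resid = np.abs(S @ v).max() if S.size else 0.0
    if resid > ss_tol:
        raise DomainError(f"steady-state violation |S v| = {resid:g} > {ss_tol:g}")
    if np.any(v < lb - tol.bounds - 1e-12) or np.any(v > ub + tol.bounds + 1e-12):
        bad = [
            model.reactions[i].id
            for i in range(len(v))
            if v[i] < lb[i] - tol.bounds - 1e-12 or v[i] > ub[i] + tol.bounds + 1e-12
        ]
        raise DomainError(f"bound violation on {bad[:5]}")


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

def _validate_model(model: cobra.Model) -> cobra.Model:
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise FormatError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        if not rxn.metabolites and not rxn.id.startswith(("EX_", SINK_PREFIX, "DM_")):
            # empty stoichiometry tolerated only for boundary-style reactions
            pass
    for met in model.metabolites:
        if not met.compartment:
            raise FormatError(f"metabolite {met.id}: empty compartment")
    if not biomass_reaction_id(model):
        raise ConfigurationError("model declares no objective reaction")
    return model


def biomass_reaction_id(model: cobra.Model) -> str | None:
    """Id of the (single) objective reaction, or None."""
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(model)
    if not coeffs:
        return None
    return max(coeffs, key=lambda r: abs(coeffs[r])).id


def load_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Load an SBML (L3+FBC) or COBRA-JSON metabolic model.

    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    fmt = format or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    try:
        if fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        elif fmt == "json":
            import json

            raw = json.loads(path.read_text())
            for rxn in raw.get("reactions", []):
                lo = rxn.get("lower_bound", 0)
                hi = rxn.get("upper_bound", 0)
                if lo > hi:
                    raise FormatError(
                        f"reaction {rxn.get('id', '?')}: lower bound {lo} "
                        f"exceeds upper bound {hi}"
                    )
            model = cobra.io.load_json_model(str(path))
        else:
            raise FormatError(f"unknown model format: {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # parse errors from libsbml / json
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _validate_model(model)


def save_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise FormatError(f"unknown model format: {fmt!r}")


# ---------------------------------------------------------------------------
# LP machinery
# ---------------------------------------------------------------------------

def fba(
    model: cobra.Model,
    objective: str | None = None,
    sense: str = "max",
) -> tuple[FluxVector, float]:
    """Flux balance analysis: optimize one reaction subject to S v = 0 and
    bounds. Returns the optimal flux vector and the LP optimum."""
    if sense not in {"max", "min"}:
        raise DomainError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        if objective is not None:
            if objective not in model.reactions:
                raise ModelLookupError(f"unknown reaction: {objective}")
            model.objective = objective
        model.objective_direction = "max" if sense == "max" else "min"
        sol = model.optimize()
        if sol.status != "optimal":
            raise InfeasibleError(
                f"FBA did not reach optimality (status={sol.status})",
                hint="check exchange bounds and steady-state consistency",
            )
        fv = FluxVector(sol.fluxes.copy(), label="reference")
        return fv, float(sol.objective_value)


def fva(
    model: cobra.Model,
    objective: str | None = None,
    fraction: float = 1.0,
) -> pd.DataFrame:
    """Flux variability analysis at a fraction of the objective optimum.

    Returns a DataFrame indexed by reaction id with ``minimum`` / ``maximum``
    columns. ``fraction=0`` yields plain bounds-constrained ranges.
    """
    if not 0 <= fraction <= 1:
        raise DomainError(f"fraction must lie in [0,1], got {fraction}")
    from cobra.flux_analysis import flux_variability_analysis

    with model:
        if objective is not None:
            model.objective = objective
        try:
            res = flux_variability_analysis(
                model, fraction_of_optimum=fraction, processes=1
            )
        except Exception as exc:
            raise InfeasibleError(f"FVA failed: {exc}") from exc
    return res[["minimum", "maximum"]]


# ---------------------------------------------------------------------------
# Gene-reaction rules
# ---------------------------------------------------------------------------

def _eval_gpr_node(node, gene_values: Mapping[str, float]):
    """Recursive GPR evaluation: AND -> min, OR -> max.

    Genes absent from ``gene_values`` carry no information: the leaf is
    dropped from its connective, and a rule whose leaves are all missing
    evaluates to None ("unknown").
    """
    if isinstance(node, ast.Name):
        return gene_values.get(node.id)
    if isinstance(node, ast.BoolOp):
        parts = [_eval_gpr_node(v, gene_values) for v in node.values]
        known = [p for p in parts if p is not None]
        if not known:
            return None
        return min(known) if isinstance(node.op, ast.And) else max(known)
    if isinstance(node, ast.Expr):
        return _eval_gpr_node(node.value, gene_values)
    raise FormatError(f"malformed gene rule node: {ast.dump(node)}")


def _gpr_root(rule):
    if isinstance(rule, str):
        rule = GPR.from_string(rule)
    body = rule.body
    if isinstance(body, list):
        if not body:
            return None
        body = body[0]
    return body


def evaluate_gpr(rule, gene_values: Mapping[str, float]) -> float | None:
    """Aggregate per-gene scores onto a reaction through its GPR.

    AND combines by minimum (a complex is limited by its scarcest subunit),
    OR by maximum (isozymes are interchangeable). Accepts a
    :class:`cobra.core.gene.GPR` or a rule string. Returns None when the
    rule is empty or no leaf gene has a value.
    """
    root = _gpr_root(rule)
    if root is None:
        return None
    return _eval_gpr_node(root, gene_values)


def gpr_is_active(rule, removed_genes: set[str]) -> bool:
    """Boolean activity of a rule when ``removed_genes`` are knocked out.

    Empty rules are always active (no genetic evidence against the
    reaction).
    """
    root = _gpr_root(rule)
    if root is None:
        return True
    if isinstance(rule, str):
        rule = GPR.from_string(rule)
    return bool(rule.eval(knockouts=removed_genes))


def genes_to_reactions(model: cobra.Model, gene_id: str) -> set[str]:
    """Reactions whose GPR references ``gene_id`` (empty set if none)."""
    if gene_id not in model.genes:
        return set()
    return {r.id for r in model.genes.get_by_id(gene_id).reactions}


# ---------------------------------------------------------------------------
# Bound edits
# ---------------------------------------------------------------------------

def knockdown_bounds(
    model: cobra.Model,
    gene_id: str,
    fraction: float,
    anchor: FluxVector,
) -> cobra.Model:
    """Cap the flux of a gene's reactions at ``fraction`` of the anchor flux.

    The bound on the side of the anchor flux's sign is constrained to
    ``fraction * |anchor|``; the opposite direction keeps its original
    bound. A zero anchor closes the forward direction (ub = 0). Returns a
    copy; the input model is not mutated.
    """
    if not 0 <= fraction <= 1:
        raise DomainError(f"knockdown fraction must lie in [0,1], got {fraction}")
    kd = model.copy()
    for rid in genes_to_reactions(model, gene_id):
        rxn = kd.reactions.get_by_id(rid)
        a = anchor[rid] if rid in anchor.values.index else 0.0
        if a >= 0:
            new_ub = min(rxn.upper_bound, fraction * a)
            rxn.lower_bound = min(rxn.lower_bound, new_ub)
            rxn.upper_bound = new_ub
        else:
            new_lb = max(rxn.lower_bound, fraction * a)
            rxn.upper_bound = max(rxn.upper_bound, new_lb)
            rxn.lower_bound = new_lb
    return kd


def sink_id(metabolite_id: str) -> str:
    return f"{SINK_PREFIX}{metabolite_id}"


def add_sink(
    model: cobra.Model,
    metabolite_id: str,
    bound: float = DEFAULT_SINK_BOUND,
) -> str:
    """Ensure an irreversible sink ``SK_<met>: met ->`` exists; return its id.

    Idempotent: re-adding returns the existing sink unchanged. The model is
    modified in place.
    """
    if metabolite_id not in model.metabolites:
        raise ModelLookupError(f"unknown metabolite: {metabolite_id}")
    sid = sink_id(metabolite_id)
    if sid in model.reactions:
        return sid
    met = model.metabolites.get_by_id(metabolite_id)
    rxn = cobra.Reaction(sid, lower_bound=0.0, upper_bound=bound)
    rxn.add_metabolites({met: -1.0})
    model.add_reactions([rxn])
    return sid
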