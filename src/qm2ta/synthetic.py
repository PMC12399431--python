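"""Synthetic fixtures and independent brute-force oracles.

Everything the test-bench needs: deterministic toy metabolic models, a
seeded random-model generator, adaptation scenarios with known ground
truth emulating the statistical shape of differential-expression /
differential-metabolite tables (fold changes with FDR-adjusted p-values,
a significant subset below the gate), and exact LP/QP solvers based on
exhaustive enumeration that serve as references for the production
solvers on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    GenerationError,
    InfeasibleError,
    NumericalError,
    UnboundedError,
)
from .model_core import (
    FluxVector,
    genes_to_reactions,
    model_bounds,
    stoichiometric_matrix,
)
from .qp import DiagQP, solve_diag_qp


# ---------------------------------------------------------------------------
# Toy models
# ---------------------------------------------------------------------------

def _reaction(model, rid, stoich, lb, ub, gpr="", subsystem=""):
    rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites(
        {model.metabolites.get_by_id(m): c for m, c in stoich.items()}
    )
    if gpr:
        rxn.gene_reaction_rule = gpr
    if subsystem:
        rxn.subsystem = subsystem
    return rxn


def make_toy6() -> cobra.Model:
    """The canonical 6-reaction fixture.

    EX_A (uptake of A, [0,10]); R1: A->B (g1); R2: A->C (g2);
    R3: B->C (g3); EX_B (export of B); BM: C-> (objective). All routes
    funnel carbon into the biomass precursor C, so max biomass equals the
    uptake bound.
    """
    model = cobra.Model("toy6")
    model.add_metabolites(
        [cobra.Metabolite(m, compartment="c") for m in ("A", "B", "C")]
    )
    _reaction(model, "EX_A", {"A": 1}, 0, 10, subsystem="exchange")
    _reaction(model, "R1", {"A": -1, "B": 1}, 0, 1000, gpr="g1", subsystem="upper")
    _reaction(model, "R2", {"A": -1, "C": 1}, 0, 1000, gpr="g2", subsystem="lower")
    _reaction(model, "R3", {"B": -1, "C": 1}, 0, 1000, gpr="g3", subsystem="upper")
    _reaction(model, "EX_B", {"B": -1}, 0, 1000, subsystem="exchange")
    _reaction(model, "BM", {"C": -1}, 0, 1000, subsystem="biomass")
    model.objective = "BM"
    return model


def make_route_model(n_routes: int = 10, route_ub: float = 10.0) -> cobra.Model:
    """Parallel-route fixture: n interchangeable enzymes convert A to B.

    EX_A (uptake, [0, 2n]); R01..Rn: A->B, each catalyzed by its own gene
    g01..gn with bound [0, route_ub]; BM: B-> (objective). Redundant routes
    make single-gene knockdowns survivable, which is what a target screen
    needs to discriminate: only the gene whose flux the omics say rose
    resists rerouting.
    """
    if n_routes < 2:
        raise DomainError("need at least two routes")
    model = cobra.Model(f"routes{n_routes}")
    model.add_metabolites(
        [cobra.Metabolite(m, compartment="c") for m in ("A", "B")]
    )
    uptake = 2.0 * n_routes
    _reaction(model, "EX_A", {"A": 1}, 0, uptake, subsystem="exchange")
    width = len(str(n_routes))
    for k in range(1, n_routes + 1):
        _reaction(
            model,
            f"R{k:0{width}d}",
            {"A": -1, "B": 1},
            0,
            route_ub,
            gpr=f"g{k:0{width}d}",
            subsystem="conversion",
        )
    _reaction(model, "BM", {"B": -1}, 0, uptake, subsystem="biomass")
    model.objective = "BM"
    return model


@dataclass
class ToySpec:
    """Recipe for a seeded random toy model."""

    n_internal_metabolites: int = 4
    n_reactions: int = 10
    n_genes: int = 6
    reversibility: float = 0.25
    pathways: tuple[str, ...] = ("glycolysis", "tca")
    seed: int = 0
    bound: float = 10.0


def make_random_model(spec: ToySpec, max_retries: int = 20) -> cobra.Model:
    """Feasible, bounded, mass-balanced random model with GPRs.

    A linear backbone (uptake -> M1 -> ... -> Mk -> biomass) guarantees a
    positive biomass optimum; extra reactions connect random metabolite
    pairs, a fraction of them reversible. Identical specs generate
    identical models.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        model = _random_model_once(spec, rng)
        sol = model.slim_optimize(error_value=None)
        if sol is not None and sol > 1e-6:
            return model
    raise GenerationError(f"no feasible model after {max_retries} retries: {spec}")


def _random_model_once(spec: ToySpec, rng: np.random.Generator) -> cobra.Model:
    k = spec.n_internal_metabolites
    model = cobra.Model(f"random{spec.seed}")
    mets = [f"M{j + 1}" for j in range(k)]
    model.add_metabolites([cobra.Metabolite(m, compartment="c") for m in mets])
    B = spec.bound
    _reaction(model, "EX_in", {mets[0]: 1}, 0, B, subsystem="exchange")
    n_backbone = k - 1
    genes = [f"g{j + 1}" for j in range(spec.n_genes)]
    ridx = 0

    def next_gpr():
        nonlocal ridx
        g1 = genes[ridx % len(genes)]
        roll = rng.random()
        if roll < 0.2:
            g2 = genes[(ridx + 1) % len(genes)]
            rule = f"{g1} and {g2}"
        elif roll < 0.4:
            g2 = genes[(ridx + 1) % len(genes)]
            rule = f"{g1} or {g2}"
        else:
            rule = g1
        ridx += 1
        return rule

    count = 0
    for j in range(n_backbone):
        rev = rng.random() < spec.reversibility
        _reaction(
            model,
            f"R{count + 1}",
            {mets[j]: -1, mets[j + 1]: 1},
            -B if rev else 0,
            B,
            gpr=next_gpr(),
            subsystem=spec.pathways[count % len(spec.pathways)],
        )
        count += 1
    n_extra = max(spec.n_reactions - n_backbone - 2, 0)
    for _ in range(n_extra):
        i, j = rng.choice(k, size=2, replace=False)
        rev = rng.random() < spec.reversibility
        _reaction(
            model,
            f"R{count + 1}",
            {mets[i]: -1, mets[j]: 1},
            -B if rev else 0,
            B,
            gpr=next_gpr(),
            subsystem=spec.pathways[count % len(spec.pathways)],
        )
        count += 1
    _reaction(model, "BM", {mets[-1]: -1}, 0, B, subsystem="biomass")
    model.objective = "BM"
    return model


# ---------------------------------------------------------------------------
# Adaptation scenarios
# ---------------------------------------------------------------------------

@dataclass
class AdaptationScenario:
    """Ground-truth flux perturbation plus the omics noise model.

    The adapted state multiplies the perturbed genes' reaction fluxes by
    ``effect_size`` while reactions without gene rules (exchanges, biomass)
    are held at their reference value, so the adaptation is an internal
    redistribution at conserved exchange. Fold changes receive
    multiplicative lognormal noise (sigma on log FC); p-values are drawn,
    not computed: measures whose flux actually changed get
    p ~ U(1e-4, p_th/2) (significant), unchanged ones p ~ U(p_th, 1).
    """

    perturbed_genes: tuple[str, ...]
    effect_size: float = 2.0
    fc_sigma: float = 0.1
    p_th: float = 0.25
    seed: int = 0
    measured_metabolites: tuple[str, ...] = ()


def simulate_adaptation(
    model: cobra.Model,
    v_ref: FluxVector,
    scenario: AdaptationScenario,
) -> tuple[FluxVector, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (v_adapted, gene table, metabolite table, ground truth).

    Raises :class:`GenerationError` when the requested effect is not
    realizable inside the model's bounds.
    """
    rng = np.random.default_rng(scenario.seed)
    vref = v_ref.reindex_like(model).values
    lb, ub = model_bounds(model)
    ids = [r.id for r in model.reactions]
    index = {rid: i for i, rid in enumerate(ids)}

    fixed: dict[int, float] = {}
    for g in scenario.perturbed_genes:
        rxns = genes_to_reactions(model, g)
        if not rxns:
            raise GenerationError(f"perturbed gene {g} catalyzes no reaction")
        for rid in rxns:
            i = index[rid]
            target = scenario.effect_size * vref[rid]
            if target < lb[i] - 1e-9 or target > ub[i] + 1e-9:
                raise GenerationError(
                    f"effect {scenario.effect_size} on {rid} leaves bounds"
                )
            fixed[i] = target
    for rxn in model.reactions:  # pin gene-less reactions at reference
        if not rxn.gene_reaction_rule and index[rxn.id] not in fixed:
            fixed[index[rxn.id]] = float(vref[rxn.id])

    qlb, qub = lb.copy(), ub.copy()
    for i, val in fixed.items():
        qlb[i] = qub[i] = val
    S = stoichiometric_matrix(model)
    anchor = vref.values
    try:
        v, _ = solve_diag_qp(
            DiagQP(S, np.ones(len(ids)), anchor, qlb, qub,
                   const=float(anchor @ anchor))
        )
    except InfeasibleError as exc:
        raise GenerationError(f"adapted state not realizable: {exc}") from exc
    v_adapted = FluxVector(pd.Series(v, index=ids), label="qm2ta")

    tiny = 1e-12
    changed_genes: list[str] = []
    rows = []
    for gene in sorted(g.id for g in model.genes):
        rxns = sorted(genes_to_reactions(model, gene))
        tot_ref = sum(abs(vref[r]) for r in rxns)
        tot_res = sum(abs(v_adapted[r]) for r in rxns)
        ratio = tot_res / max(tot_ref, tiny)
        changed = abs(ratio - 1.0) > 1e-9
        if changed:
            changed_genes.append(gene)
        noise = float(np.exp(rng.normal(0.0, scenario.fc_sigma))) if scenario.fc_sigma > 0 else 1.0
        fc = max(ratio * noise, 1e-6)
        p = (
            float(rng.uniform(1e-4, scenario.p_th / 2))
            if changed
            else float(rng.uniform(scenario.p_th, 1.0))
        )
        rows.append(dict(measure_id=gene, kind="gene", fc=fc, p_adj=p))
    de_table = pd.DataFrame(rows)

    met_rows = []
    for met in scenario.measured_metabolites:
        sid = f"SK_{met}"
        if sid not in model.reactions:
            continue
        ratio = abs(v_adapted[sid]) / max(abs(vref[sid]), tiny)
        changed = abs(ratio - 1.0) > 1e-9
        noise = float(np.exp(rng.normal(0.0, scenario.fc_sigma))) if scenario.fc_sigma > 0 else 1.0
        p = (
            float(rng.uniform(1e-4, scenario.p_th / 2))
            if changed
            else float(rng.uniform(scenario.p_th, 1.0))
        )
        met_rows.append(
            dict(measure_id=met, kind="metabolite", fc=max(ratio * noise, 1e-6), p_adj=p)
        )
    met_table = pd.DataFrame(
        met_rows, columns=["measure_id", "kind", "fc", "p_adj"]
    )

    truth = dict(
        perturbed_genes=list(scenario.perturbed_genes),
        effect_size=scenario.effect_size,
        fc_sigma=scenario.fc_sigma,
        seed=scenario.seed,
        changed_genes=changed_genes,
    )
    return v_adapted, de_table, met_table, truth


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def qp_oracle(qp: DiagQP, max_reactions: int = 12) -> tuple[np.ndarray, float]:
    """Exact diagonal-QP optimum by exhaustive active-set enumeration.

    Every pattern of {free, at-lower, at-upper} per variable is tried; for
    each, the equality-constrained stationarity system is solved and the
    candidate kept if it is feasible. Convexity (a >= 0) makes the best
    feasible stationary point the global optimum. Exponential in the
    number of reactions; refuses instances above ``max_reactions``.
    """
    n = len(qp.lb)
    if n > max_reactions:
        raise DomainError(f"oracle limited to {max_reactions} reactions, got {n}")
    if np.any(qp.a < 0):
        raise NumericalError("indefinite objective rejected by oracle")
    if np.any(~np.isfinite(qp.lb)) or np.any(~np.isfinite(qp.ub)):
        raise UnboundedError("oracle requires finite bounds")
    S = np.atleast_2d(qp.S) if qp.S.size else np.zeros((0, n))
    m = S.shape[0]
    best_v, best_f = None, np.inf
    for pattern in itertools.product((0, 1, 2), repeat=n):
        free = [i for i in range(n) if pattern[i] == 0]
        v = np.where(np.array(pattern) == 1, qp.lb, qp.ub).astype(float)
        nf = len(free)
        if nf:
            A = np.zeros((nf + m, nf + m))
            rhs = np.zeros(nf + m)
            A[:nf, :nf] = np.diag(2.0 * qp.a[free])
            if m:
                A[:nf, nf:] = S[:, free].T
                A[nf:, :nf] = S[:, free]
                fixed_mask = np.array(pattern) != 0
                rhs[nf:] = -S[:, fixed_mask] @ v[fixed_mask]
            rhs[:nf] = 2.0 * qp.b[free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > 1e-7 * max(1.0, np.linalg.norm(rhs)):
                continue
            v[free] = sol[:nf]
        if m and np.abs(S @ v).max() > 1e-8:
            continue
        if np.any(v < qp.lb - 1e-9) or np.any(v > qp.ub + 1e-9):
            continue
        f = qp.objective(np.clip(v, qp.lb, qp.ub))
        if f < best_f - 0.0:
            best_f, best_v = f, np.clip(v, qp.lb, qp.ub)
    if best_v is None:
        raise InfeasibleError("oracle found no feasible active set")
    return best_v, best_f


def _vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """Yield vertices of {S v = 0, lb <= v <= ub} by basis enumeration.

    For each choice of n - rank(S) variables pinned at a bound, the free
    block is factored once and all 2^f corner sides are solved in a single
    batched least-squares call.
    """
    yield from _affine_vertices(
        np.atleast_2d(S) if S.size else np.zeros((0, len(lb))),
        np.zeros(np.atleast_2d(S).shape[0] if S.size else 0),
        lb,
        ub,
    )


def lp_oracle(
    S: np.ndarray,
    c: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "max",
    extra_ineq: tuple[np.ndarray, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Exact LP optimum over the flux polytope by vertex enumeration.

    ``extra_ineq = (row, floor)`` adds the half-space row . v >= floor
    (used for fraction-of-optimum constraints); both the vertices of the
    base polytope satisfying it and the vertices on its boundary are
    enumerated. Requires finite bounds.
    """
    if np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub)):
        raise UnboundedError("oracle requires finite bounds")
    sign = -1.0 if sense == "max" else 1.0
    best_v, best_f = None, np.inf

    def consider(v):
        nonlocal best_v, best_f
        if extra_ineq is not None:
            row, floor = extra_ineq
            if row @ v < floor - 1e-9:
                return
        f = sign * float(c @ v)
        if f < best_f:
            best_f, best_v = f, v

    for v in _vertices(S, lb, ub):
        consider(v)
    if extra_ineq is not None:
        row, floor = extra_ineq
        S_aug = np.vstack([np.atleast_2d(S) if S.size else np.zeros((0, len(lb))),
                           row[None, :]])
        # shift: row.v = floor -> substitute u = v with affine part handled by
        # translating one coordinate is messy; instead solve on homogeneous
        # system via a slack-free trick: enumerate bases of S v = 0 with the
        # extra row active, i.e. solve [S; row] v = [0; floor].
        for v in _affine_vertices(S_aug, np.append(np.zeros(
                np.atleast_2d(S).shape[0] if S.size else 0), floor), lb, ub):
            consider(v)
    if best_v is None:
        raise InfeasibleError("LP oracle: empty polytope")
    return best_v, sign * best_f


def _affine_vertices(A: np.ndarray, b: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """Vertices of {A v = b, lb <= v <= ub}, batched per basis choice."""
    n = len(lb)
    r = np.linalg.matrix_rank(A) if A.size else 0
    n_fixed = n - r
    if n_fixed == 0:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if (
            np.abs(A @ sol - b).max() <= 1e-8
            and np.all(sol >= lb - 1e-9)
            and np.all(sol <= ub + 1e-9)
        ):
            yield np.clip(sol, lb, ub)
        return
    # all 2^f lower/upper side patterns as one (f x 2^f) matrix
    side_masks = np.array(
        list(itertools.product((0, 1), repeat=n_fixed)), dtype=bool
    ).T  # shape (n_fixed, 2^f)
    for fixed in itertools.combinations(range(n), n_fixed):
        fixed = list(fixed)
        free = [i for i in range(n) if i not in fixed]
        corners = np.where(side_masks, ub[fixed, None], lb[fixed, None])
        rhs = b[:, None] - (A[:, fixed] @ corners if A.size else 0.0)
        if free:
            sols, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            ok = np.abs(A[:, free] @ sols - rhs).max(axis=0) <= 1e-8
            ok &= (sols >= lb[free, None] - 1e-9).all(axis=0)
            ok &= (sols <= ub[free, None] + 1e-9).all(axis=0)
        else:
            sols = np.zeros((0, corners.shape[1]))
            ok = np.abs(rhs).max(axis=0) <= 1e-8 if rhs.size else np.ones(
                corners.shape[1], dtype=bool
            )
        for k in np.where(ok)[0]:
            v = np.zeros(n)
            v[fixed] = corners[:, k]
            v[free] = sols[:, k]
            yield np.clip(v, lb, ub)


def fba_oracle(model: cobra.Model, objective: str | None = None,
               sense: str = "max") -> tuple[FluxVector, float]:
    """FBA by vertex enumeration (small models only)."""
    from .model_core import biomass_reaction_id

    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    ids = [r.id for r in model.reactions]
    obj = objective or biomass_reaction_id(model)
    c = np.array([1.0 if rid == obj else 0.0 for rid in ids])
    v, f = lp_oracle(S, c, lb, ub, sense=sense)
    return FluxVector(pd.Series(v, index=ids)), f


def fva_oracle(model: cobra.Model, fraction: float = 1.0) -> pd.DataFrame:
    """FVA by vertex enumeration with the fraction-of-optimum half-space."""
    from .model_core import biomass_reaction_id

    S = stoichiometric_matrix(model)
    lb, ub = model_bounds(model)
    ids = [r.id for r in model.reactions]
    obj = biomass_reaction_id(model)
    c_obj = np.array([1.0 if rid == obj else 0.0 for rid in ids])
    _, opt = lp_oracle(S, c_obj, lb, ub, sense="max")
    extra = (c_obj, fraction * opt)
    rows = {}
    for k, rid in enumerate(ids):
        c = np.zeros(len(ids))
        c[k] = 1.0
        _, vmin = lp_oracle(S, c, lb, ub, sense="min", extra_ineq=extra)
        _, vmax = lp_oracle(S, c, lb, ub, sense="max", extra_ineq=extra)
        rows[rid] = dict(minimum=vmin, maximum=vmax)
    return pd.DataFrame.from_dict(rows, orient="index")
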