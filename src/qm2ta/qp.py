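"""Separable convex QP solver over the flux polytope.

Both the multiomic transformation objective and MOMA reduce to

    min  sum_i a_i v_i^2 - 2 b_i v_i + const
    s.t. S v = 0,  lb <= v <= ub

with a_i >= 0 (diagonal positive-semidefinite Hessian). The problem is
solved with scipy's ``trust-constr`` from an LP-feasible starting point;
the returned point is re-validated against the constraints and the
objective is recomputed independently of the solver's reported value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .exceptions import InfeasibleError, NumericalError


@dataclass
class DiagQP:
    """min v' diag(a) v - 2 b' v + const  s.t.  S v = 0, lb <= v <= ub."""

    S: np.ndarray
    a: np.ndarray
    b: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    const: float = 0.0

    def objective(self, v: np.ndarray) -> float:
        return float(self.a @ (v * v) - 2.0 * self.b @ v + self.const)


def feasible_point(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Any point of {S v = 0, lb <= v <= ub}, via an LP phase-1 solve."""
    n = len(lb)
    kwargs = {}
    if S.size:
        kwargs = dict(A_eq=S, b_eq=np.zeros(S.shape[0]))
    res = linprog(np.zeros(n), bounds=list(zip(lb, ub)), method="highs", **kwargs)
    if res.status != 0:
        raise InfeasibleError(
            "no feasible flux satisfies the steady-state and bound constraints",
            hint=res.message,
        )
    return np.clip(res.x, lb, ub)


def solve_diag_qp(
    qp: DiagQP,
    x0: np.ndarray | None = None,
    gtol: float = 1e-12,
    constraint_tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Solve the QP; returns (v, objective value at v).

    Raises :class:`InfeasibleError` when the polytope is empty and
    :class:`NumericalError` when the solver stops without an acceptably
    feasible iterate.
    """
    if np.any(qp.a < -1e-12):
        raise NumericalError("indefinite objective: negative curvature entries")
    a = np.maximum(qp.a, 0.0)
    n = len(qp.lb)
    if x0 is None:
        x0 = feasible_point(qp.S, qp.lb, qp.ub)

    # fast path: SLSQP + exact active-set polish, accepted only with a
    # verified KKT certificate (convexity then guarantees global optimality)
    v_fast = _try_slsqp(qp, a, x0, constraint_tol)
    if v_fast is not None:
        return v_fast, qp.objective(v_fast)

    def f(v):
        return a @ (v * v) - 2.0 * qp.b @ v

    def grad(v):
        return 2.0 * (a * v - qp.b)

    H = np.diag(2.0 * a)

    constraints = []
    if qp.S.size:
        constraints.append(LinearConstraint(qp.S, 0.0, 0.0))
    res = minimize(
        f,
        x0,
        jac=grad,
        hess=lambda v: H,
        method="trust-constr",
        bounds=Bounds(qp.lb, qp.ub),
        constraints=constraints,
        options=dict(gtol=gtol, xtol=1e-14, maxiter=5000, verbose=0),
    )
    v = np.clip(res.x, qp.lb, qp.ub)
    # Polish: read the active set off the iterate and solve its KKT system
    # exactly; keeps whichever point is feasible with the lower objective.
    for active_tol in (1e-10, 1e-7, 1e-5, 1e-4, 1e-3):
        polished = _polish_active_set(qp, a, v, active_tol, constraint_tol)
        if polished is not None and qp.objective(polished) < qp.objective(v) + 1e-15:
            v = polished
    resid = np.abs(qp.S @ v).max() if qp.S.size else 0.0
    if resid > constraint_tol:
        # one exact projection back onto the affine subspace, then re-clip
        v = _project_equality(v, qp.S)
        v = np.clip(v, qp.lb, qp.ub)
        resid = np.abs(qp.S @ v).max() if qp.S.size else 0.0
        if resid > constraint_tol:
            raise NumericalError(
                f"QP solver left |S v| = {resid:g} (status {res.status}: {res.message})"
            )
    return v, qp.objective(v)  # objective recomputed at v, not trusted from the solver


def _try_slsqp(
    qp: DiagQP, a: np.ndarray, x0: np.ndarray, constraint_tol: float
) -> np.ndarray | None:
    """SLSQP solve followed by KKT-certified polishing; None on failure."""
    constraints = (
        [dict(type="eq", fun=lambda v: qp.S @ v, jac=lambda v: qp.S)]
        if qp.S.size
        else []
    )
    res = minimize(
        lambda v: a @ (v * v) - 2.0 * qp.b @ v,
        x0,
        jac=lambda v: 2.0 * (a * v - qp.b),
        method="SLSQP",
        bounds=list(zip(qp.lb, qp.ub)),
        constraints=constraints,
        options=dict(maxiter=500, ftol=1e-14),
    )
    if not np.all(np.isfinite(res.x)):
        return None
    v = np.clip(res.x, qp.lb, qp.ub)
    for active_tol in (1e-9, 1e-7, 1e-5, 1e-4):
        polished = _polish_active_set(qp, a, v, active_tol, constraint_tol)
        if polished is not None and _kkt_certificate(qp, a, polished):
            return polished
    return None


def _kkt_certificate(
    qp: DiagQP, a: np.ndarray, v: np.ndarray, tol: float = 1e-7
) -> bool:
    """Verify stationarity and dual feasibility at a candidate point."""
    n = len(v)
    S = qp.S if qp.S.size else np.zeros((0, n))
    g = 2.0 * (a * v - qp.b)
    scale = max(1.0, np.abs(g).max())
    at_lb = v <= qp.lb + 1e-8
    at_ub = v >= qp.ub - 1e-8
    free = ~(at_lb | at_ub)
    if S.shape[0]:
        lam, *_ = np.linalg.lstsq(S[:, free].T if free.any() else S.T,
                                  -(g[free] if free.any() else g), rcond=None)
        reduced = g + S.T @ lam
    else:
        reduced = g
    if free.any() and np.abs(reduced[free]).max() > tol * scale:
        return False
    # at an upper bound the reduced gradient must push upward (mu >= 0),
    # at a lower bound downward; pinned variables (lb == ub) are exempt
    pinned = qp.ub - qp.lb <= 1e-12
    bad_ub = at_ub & ~pinned & (reduced > tol * scale)
    bad_lb = at_lb & ~pinned & (reduced < -tol * scale)
    return not (bad_ub.any() or bad_lb.any())


def _polish_active_set(
    qp: DiagQP,
    a: np.ndarray,
    v: np.ndarray,
    active_tol: float,
    constraint_tol: float,
) -> np.ndarray | None:
    """Exact KKT solve for the active set suggested by an iterate.

    Returns the polished point, or None when it is not feasible.
    """
    n = len(v)
    S = qp.S if qp.S.size else np.zeros((0, n))
    m = S.shape[0]
    at_lb = v <= qp.lb + active_tol
    at_ub = v >= qp.ub - active_tol
    free = np.where(~(at_lb | at_ub))[0]
    fixed_v = np.where(at_lb, qp.lb, np.where(at_ub, qp.ub, 0.0))
    nf = len(free)
    A = np.zeros((nf + m, nf + m))
    rhs = np.zeros(nf + m)
    A[:nf, :nf] = np.diag(2.0 * a[free])
    rhs[:nf] = 2.0 * qp.b[free]
    if m:
        A[:nf, nf:] = S[:, free].T
        A[nf:, :nf] = S[:, free]
        fixed_mask = at_lb | at_ub
        rhs[nf:] = -S[:, fixed_mask] @ fixed_v[fixed_mask]
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if np.linalg.norm(A @ sol - rhs) > 1e-8 * max(1.0, np.linalg.norm(rhs)):
        return None
    out = fixed_v.copy()
    out[free] = sol[:nf]
    if np.any(out < qp.lb - 1e-9) or np.any(out > qp.ub + 1e-9):
        return None
    if m and np.abs(S @ out).max() > constraint_tol:
        return None
    return np.clip(out, qp.lb, qp.ub)


def _project_equality(v: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Orthogonal projection of v onto {S v = 0}."""
    if not S.size:
        return v
    correction, *_ = np.linalg.lstsq(S, S @ v, rcond=None)
    return v - correction
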