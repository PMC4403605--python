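"""Linear-programming core: FBA, FVA and minimal-active-set estimation.

All solves go through scipy's HiGHS interface with tight feasibility and
optimality tolerances (1e-9), single-threaded and with a fixed constraint
ordering, so degenerate optima are reported reproducibly (the contract is the
flux *range*, not a particular vertex).  Every reported optimum is verified
against the dual objective (strong duality) to 1e-7 relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import InfeasibleProblem, StructuralError, UnboundedProblem
from .model import MetabolicModel, build_stoich_matrix

#: solver feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: absolute slack used when fixing a flux at a previously computed optimum
FIX_SLACK = 1e-9
#: fluxes below this magnitude are treated as zero when counting active reactions
ACTIVE_TOL = 1e-9


@dataclass(frozen=True)
class LinearConstraint:
    """A linear relation ``sum(coeffs[r] * v_r) <sense> rhs`` over fluxes."""

    coeffs: Mapping[str, float]
    sense: str = "=="          # "==", "<=", ">="
    rhs: float = 0.0

    def __post_init__(self):
        if self.sense not in ("==", "<=", ">="):
            raise ValueError(f"bad constraint sense {self.sense!r}")
        if not self.coeffs:
            raise ValueError("constraint has no terms")


@dataclass
class FluxSolution:
    """An optimal flux distribution."""

    fluxes: dict[str, float]
    objective_value: float
    status: str = "optimal"    # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass(frozen=True)
class FluxRange:
    """A per-reaction flux variability interval."""

    min: float
    max: float

    def __post_init__(self):
        if self.min > self.max + 1e-6:
            raise ValueError(f"FluxRange min {self.min} > max {self.max}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min + self.max)

    def contains(self, value: float, tol: float = 1e-6) -> bool:
        return self.min - tol <= value <= self.max + tol


class _Assembled:
    """Reusable LP data for one model + extra-constraint set."""

    def __init__(self, model: MetabolicModel,
                 extra_constraints: Sequence[LinearConstraint] = ()):
        self.model = model
        self.index = {r.id: j for j, r in enumerate(model.reactions)}
        self.n = len(model.reactions)
        S = build_stoich_matrix(model)
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        eq_rows, eq_rhs = [S], [np.zeros(S.shape[0])]
        ub_rows, ub_rhs = [], []
        for con in extra_constraints:
            row = np.zeros(self.n)
            for rid, coeff in con.coeffs.items():
                if rid not in self.index:
                    raise StructuralError(
                        f"constraint references unknown reaction {rid!r}")
                row[self.index[rid]] = coeff
            if con.sense == "==":
                eq_rows.append(row.reshape(1, -1))
                eq_rhs.append(np.array([con.rhs]))
            elif con.sense == "<=":
                ub_rows.append(row)
                ub_rhs.append(con.rhs)
            else:  # >=
                ub_rows.append(-row)
                ub_rhs.append(-con.rhs)
        from scipy import sparse

        self.A_eq = sparse.vstack([sparse.csr_matrix(b) for b in eq_rows], format="csr")
        self.b_eq = np.concatenate(eq_rhs)
        self.A_ub = np.array(ub_rows) if ub_rows else None
        self.b_ub = np.array(ub_rhs) if ub_rhs else None

    def objective_vector(self, objective: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(self.n)
        for rid, w in objective.items():
            if rid not in self.index:
                raise StructuralError(f"objective references unknown reaction {rid!r}")
            c[self.index[rid]] = w
        return c

    def solve(self, c_min: np.ndarray, lb=None, ub=None):
        res = linprog(
            c_min, A_eq=self.A_eq, b_eq=self.b_eq,
            A_ub=self.A_ub, b_ub=self.b_ub,
            bounds=np.column_stack([self.lb if lb is None else lb,
                                    self.ub if ub is None else ub]),
            method="highs",
            options={"presolve": True,
                     "primal_feasibility_tolerance": SOLVER_TOL,
                     "dual_feasibility_tolerance": SOLVER_TOL})
        return res


def _dual_objective(res, assembled: _Assembled, lb, ub) -> float:
    """Dual objective from HiGHS marginals (for the strong-duality check)."""
    total = float(np.dot(res.eqlin.marginals, assembled.b_eq))
    if assembled.b_ub is not None:
        total += float(np.dot(res.ineqlin.marginals, assembled.b_ub))
    for marg, bound in ((res.lower.marginals, lb), (res.upper.marginals, ub)):
        active = np.abs(marg) > 1e-12
        if np.any(active):
            contrib = marg[active] * bound[active]
            contrib = contrib[np.isfinite(contrib)]
            total += float(np.sum(contrib))
    return total


def _raise_for_status(res, context: str = ""):
    if res.status == 2:
        raise InfeasibleProblem(f"LP infeasible{': ' + context if context else ''}")
    if res.status == 3:
        raise UnboundedProblem(f"LP unbounded{': ' + context if context else ''}")
    if res.status != 0:
        raise InfeasibleProblem(f"solver failure (status {res.status}): {res.message}")


def solve_fba(model: MetabolicModel,
              objective: Mapping[str, float] | str | None = None,
              direction: str = "max",
              extra_constraints: Sequence[LinearConstraint] = (),
              check_duality: bool = True,
              _assembled: _Assembled | None = None) -> FluxSolution:
    """Flux-balance analysis: optimize a linear objective over S v = 0, lb <= v <= ub.

    ``objective`` may be a reaction id, a reaction-id -> weight map, or None to
    use the model's stored objective.  Infeasible or unbounded problems raise
    rather than returning a zeroed solution.
    """
    if objective is None:
        objective = model.objective
    if isinstance(objective, str):
        objective = {objective: 1.0}
    if not objective:
        raise StructuralError("no objective given and model has none")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    asm = _assembled or _Assembled(model, extra_constraints)
    sign = -1.0 if direction == "max" else 1.0
    c = sign * asm.objective_vector(objective)
    res = asm.solve(c)
    _raise_for_status(res, f"objective {sorted(objective)}")
    if check_duality:
        dual = _dual_objective(res, asm, asm.lb, asm.ub)
        gap = abs(res.fun - dual) / max(1.0, abs(res.fun))
        if gap > 1e-7:
            raise InfeasibleProblem(
                f"duality gap {gap:.2e} exceeds 1e-7; solution unreliable")
    fluxes = {r.id: float(res.x[j]) for j, r in enumerate(model.reactions)}
    _check_steady_state(asm, res.x)
    return FluxSolution(fluxes, float(sign * res.fun))


def _check_steady_state(asm: _Assembled, v: np.ndarray) -> None:
    residual = np.abs(asm.A_eq @ v - asm.b_eq).max() if asm.A_eq.shape[0] else 0.0
    scale = max(1.0, float(np.abs(v).max()))
    if residual > 1e-6 * scale:  # solver tolerance is 1e-9; guard against drift
        raise InfeasibleProblem(f"steady-state residual {residual:.2e} too large")


def run_fva(model: MetabolicModel,
            fixed: Iterable[tuple[str, float]] = (),
            targets: Sequence[str] | None = None,
            extra_constraints: Sequence[LinearConstraint] = (),
            slack: float = FIX_SLACK) -> dict[str, FluxRange]:
    """Flux-variability analysis.

    Each reaction in ``fixed`` is pinned to its value (within an absolute
    ``slack``, default 1e-9, to avoid numerical infeasibility); the min and max
    of every target flux over the resulting polytope are returned
    (2 * len(targets) LP solves).
    """
    asm = _Assembled(model, extra_constraints)
    lb, ub = asm.lb.copy(), asm.ub.copy()
    for rid, value in fixed:
        if rid not in asm.index:
            raise StructuralError(f"cannot fix unknown reaction {rid!r}")
        j = asm.index[rid]
        lb[j], ub[j] = value - slack, value + slack
    if targets is None:
        targets = [r.id for r in model.reactions]
    out: dict[str, FluxRange] = {}
    for rid in targets:
        j = asm.index[rid]
        c = np.zeros(asm.n)
        bounds_lohi = []
        for sense in (1.0, -1.0):
            c[j] = sense
            res = asm.solve(c, lb=lb, ub=ub)
            if res.status != 0:
                fixed_ids = ", ".join(r for r, _ in fixed) or "none"
                _raise_for_status(
                    res, f"FVA for {rid} (fixed fluxes: {fixed_ids})")
            bounds_lohi.append(float(sense * res.fun))
        c[j] = 0.0
        lo, hi = bounds_lohi
        out[rid] = FluxRange(min(lo, hi), max(lo, hi))
    return out


def minimal_active_set(model: MetabolicModel,
                       objective: Mapping[str, float] | str,
                       objective_optimum: float,
                       extra_constraints: Sequence[LinearConstraint] = (),
                       tol: float = ACTIVE_TOL) -> tuple[int, FluxSolution]:
    """Count reactions needed at the optimum by minimizing total absolute flux.

    With the objective pinned at ``objective_optimum`` (within the standard
    slack), the sum of absolute fluxes is minimized; futile cycles that are
    flux-degenerate at the optimum therefore carry zero flux.  Returns the
    number of reactions with |v| > tol together with the parsimonious flux
    distribution.  Isoenzymes should be collapsed beforehand for a meaningful
    count.
    """
    if isinstance(objective, str):
        objective = {objective: 1.0}
    asm = _Assembled(model, tuple(extra_constraints) + (
        LinearConstraint(objective, ">=", objective_optimum - FIX_SLACK),))
    # variables: v (n) then t (n) with t >= |v|; minimize sum(t)
    n = asm.n
    from scipy import sparse

    A_eq = sparse.hstack([asm.A_eq, sparse.csr_matrix((asm.A_eq.shape[0], n))],
                         format="csr")
    eye = sparse.identity(n, format="csr")
    abs_rows = sparse.vstack([sparse.hstack([eye, -eye]),
                              sparse.hstack([-eye, -eye])], format="csr")
    blocks = [abs_rows]
    rhs = [np.zeros(2 * n)]
    if asm.A_ub is not None:
        blocks.append(sparse.hstack(
            [sparse.csr_matrix(asm.A_ub), sparse.csr_matrix((len(asm.b_ub), n))]))
        rhs.append(asm.b_ub)
    A_ub = sparse.vstack(blocks, format="csr")
    b_ub = np.concatenate(rhs)
    bounds = np.column_stack([
        np.concatenate([asm.lb, np.zeros(n)]),
        np.concatenate([asm.ub, np.full(n, np.inf)])])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                  A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs",
                  options={"presolve": True,
                           "primal_feasibility_tolerance": SOLVER_TOL,
                           "dual_feasibility_tolerance": SOLVER_TOL})
    _raise_for_status(res, "total-flux minimization")
    v = res.x[:n]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    count = int(np.sum(np.abs(v) > tol))
    value = float(sum(w * fluxes[rid] for rid, w in objective.items()))
    return count, FluxSolution(fluxes, value)
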