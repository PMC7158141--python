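"""A minimal solver-agnostic linear-programming layer.

Every algorithm in the package funnels through :func:`solve_lp`, so a
single :class:`LPSession` can count LP solves — the LP count is a
first-class observable of the fast consistency checker and of the
reconstruction loop.

The canonical form is

    minimize    c' z
    subject to  A_eq z  = b_eq
                A_ub z <= b_ub
                lb <= z <= ub   (entries may be +-inf)

with inequalities in <=-convention only; builders convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "LinearProgram",
    "LPSolution",
    "LPStatus",
    "LPSession",
    "solve_lp",
    "SolverError",
    "available_solvers",
]


class SolverError(RuntimeError):
    """The LP backend failed numerically (never returns garbage)."""


class LPStatus(Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    NUMERIC_FAILURE = "numeric_failure"


@dataclass
class LinearProgram:
    objective: np.ndarray
    A_eq: Optional[sp.spmatrix] = None
    b_eq: Optional[np.ndarray] = None
    A_ub: Optional[sp.spmatrix] = None
    b_ub: Optional[np.ndarray] = None
    lb: Optional[np.ndarray] = None  # default 0 would be a trap: default -inf
    ub: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.objective = np.asarray(self.objective, dtype=float).ravel()
        nvar = self.objective.size
        if self.lb is None:
            self.lb = np.full(nvar, -np.inf)
        if self.ub is None:
            self.ub = np.full(nvar, np.inf)
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        for A, b, tag in ((self.A_eq, self.b_eq, "equality"),
                          (self.A_ub, self.b_ub, "inequality")):
            if (A is None) != (b is None):
                raise ValueError(f"{tag} matrix and rhs must come together")
            if A is not None:
                if A.shape[1] != nvar:
                    raise ValueError(f"{tag} matrix has wrong variable dim")
                if not np.all(np.isfinite(np.asarray(b, dtype=float))):
                    raise ValueError(f"{tag} right-hand side not finite")
        if self.lb.size != nvar or self.ub.size != nvar:
            raise ValueError("bound vectors have wrong length")

    @property
    def n_vars(self) -> int:
        return self.objective.size


@dataclass
class LPSolution:
    status: LPStatus
    primal: Optional[np.ndarray] = None
    objective_value: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status is LPStatus.OPTIMAL


# ---------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------

def _solve_highs(lp: LinearProgram) -> LPSolution:
    bounds = list(zip(
        np.where(np.isneginf(lp.lb), None, lp.lb),
        np.where(np.isposinf(lp.ub), None, lp.ub),
    ))
    res = linprog(
        lp.objective,
        A_eq=lp.A_eq, b_eq=lp.b_eq,
        A_ub=lp.A_ub, b_ub=lp.b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return LPSolution(LPStatus.OPTIMAL, np.asarray(res.x), float(res.fun))
    if res.status == 2:
        return LPSolution(LPStatus.INFEASIBLE)
    if res.status == 3:
        return LPSolution(LPStatus.UNBOUNDED)
    return LPSolution(LPStatus.NUMERIC_FAILURE)


_BACKENDS: dict[str, Callable[[LinearProgram], LPSolution]] = {
    "highs": _solve_highs,
}


def available_solvers() -> list[str]:
    return sorted(_BACKENDS)


def solve_lp(lp: LinearProgram, solver: str = "highs") -> LPSolution:
    """Solve a canonical-form LP; deterministic for a fixed backend.

    Raises
    ------
    SolverError
        If the named backend is unknown or reports numeric failure.
    """
    try:
        backend = _BACKENDS[solver]
    except KeyError:
        raise SolverError(
            f"unknown solver {solver!r}; available: {available_solvers()}"
        ) from None
    sol = backend(lp)
    if sol.status is LPStatus.NUMERIC_FAILURE:
        raise SolverError(f"solver {solver!r} failed numerically")
    return sol


@dataclass
class LPSession:
    """Instrumented wrapper counting every LP solve."""

    solver: str = "highs"
    _count: int = field(default=0, repr=False)

    def solve(self, lp: LinearProgram) -> LPSolution:
        self._count += 1
        return solve_lp(lp, solver=self.solver)

    def count_lps(self) -> int:
        return self._count
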