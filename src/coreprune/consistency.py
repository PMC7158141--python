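"""Fast flux-consistency checking (blocked-reaction detection).

A reaction is *blocked* when its flux vanishes in every steady-state
flux distribution.  Two observations make detection cheap:

1. All irreversible reactions that can ever be active can be active
   *simultaneously*: steady-state flux distributions form a cone that is
   closed under addition, so a single LP that maximizes the number of
   irreversible reactions with flux >= 1 finds the unique maximal
   irreversible support.  Every irreversible reaction outside it is
   blocked.
2. Given such a dense witness ``v`` (positive on all retained
   irreversible reactions), a remaining reaction j is unblocked iff some
   ``u`` in the null space of the column-restricted ``S`` has
   ``u_j != 0`` — for large enough c > 0, ``u + c v`` is a steady-state
   flux distribution with reaction j active.  This is pure linear
   algebra: one rank-revealing factorization, no further LPs.

The whole check therefore costs one LP plus one SVD, independent of the
number of reactions, versus the 2n LPs of the flux-variability oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.linalg import null_space
import scipy.sparse as sp

from .config import FEASIBILITY_TOL, ZERO_TOL
from .lp import LinearProgram, LPSession, LPStatus
from .model import FluxVector, MetabolicNetwork

__all__ = [
    "ConsistencyResult",
    "maximal_irreversible_support",
    "blocked_reversibles",
    "check_consistency",
]


@dataclass
class ConsistencyResult:
    """Outcome of a consistency check."""

    blocked: frozenset[int]
    blocked_ids: list[str]
    witness_v: FluxVector
    lp_count: int
    #: populated by the partitioned entry point only
    components: Optional[list[list[int]]] = None

    @property
    def consistent(self) -> bool:
        return not self.blocked


def maximal_irreversible_support(
    net: MetabolicNetwork,
    session: Optional[LPSession] = None,
    zero_tol: float = ZERO_TOL,
) -> FluxVector:
    """One LP computing a steady-state ``v`` whose support contains
    every unblocked irreversible reaction, with flux >= 1 on each.

    maximize  sum_j z_j            over irreversible j
    s.t.      S v = 0,  v_irr >= 0,  z_j <= v_j,  z_j <= 1

    Because the steady-state cone is closed under addition, any optimum
    has z_j = 1 (hence v_j >= 1) for *every* unblockable irreversible
    reaction, so a single solve decides them all.  A guard pass
    re-solves over still-undecided reactions in the (numerically
    degenerate) event the solver returns a vertex missing support
    members; at most log2(n)+1 passes.
    """
    session = session or LPSession()
    n = net.n
    irr = np.flatnonzero(net.irreversible)
    if irr.size == 0 or n == 0:
        return FluxVector(np.zeros(n), zero_tol)

    total = np.zeros(n)
    undecided = list(irr)
    max_passes = int(math.log2(max(n, 2))) + 1
    for _ in range(max_passes):
        v, z = _support_lp(net, undecided, session)
        total += v
        # at an exact optimum z_j = 1 for every unblockable target, so
        # v_j >= 1 there; a target with z near 1 but v below tolerance
        # signals a degenerate vertex and triggers a re-solve over the
        # suspicious targets only
        suspicious = [j for j, zj in zip(undecided, z)
                      if total[j] <= zero_tol and zj > 0.5]
        undecided = suspicious
        if not undecided:
            break
    return FluxVector(total, zero_tol)


def _support_lp(net: MetabolicNetwork, targets: list[int],
                session: LPSession) -> tuple[np.ndarray, np.ndarray]:
    n = net.n
    k = len(targets)
    # variables: [v (n), z (k)]
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sp.hstack([net.S, sp.csc_matrix((net.m, k))], format="csc")
    b_eq = np.zeros(net.m)
    # z_t - v_{targets[t]} <= 0
    rows = np.arange(k)
    A_ub = sp.coo_matrix(
        (np.concatenate([np.ones(k), -np.ones(k)]),
         (np.concatenate([rows, rows]),
          np.concatenate([n + rows, np.array(targets)]))),
        shape=(k, n + k),
    ).tocsc()
    lb = np.full(n + k, -np.inf)
    lb[np.flatnonzero(net.irreversible)] = 0.0
    lb[n:] = -np.inf
    ub = np.full(n + k, np.inf)
    ub[n:] = 1.0
    sol = session.solve(LinearProgram(c, A_eq, b_eq, A_ub, np.zeros(k), lb, ub))
    if sol.status is not LPStatus.OPTIMAL:
        # v = 0 is always feasible, so anything else is a solver breakdown
        raise RuntimeError(f"support LP ended with status {sol.status}")
    return sol.primal[:n], sol.primal[n:]


def blocked_reversibles(
    net: MetabolicNetwork,
    retained: Iterable[int],
    zero_tol: float = ZERO_TOL,
    rank_tol: float = FEASIBILITY_TOL,
) -> frozenset[int]:
    """Reversible reactions among ``retained`` that are blocked.

    Decided by one null-space basis of the column-restricted ``S``
    (rank tolerance relative to the largest singular value): reaction j
    is blocked iff its row of the basis is entirely below ``zero_tol``.
    No sign constraints are needed thanks to the dense irreversible
    witness (the ``u + c v`` combination argument).
    """
    retained = sorted(set(int(j) for j in retained))
    if not retained:
        return frozenset()
    S_r = net.S[:, retained].toarray()
    basis = null_space(S_r, rcond=rank_tol)
    blocked = set()
    for p, j in enumerate(retained):
        if net.irreversible[j]:
            continue
        if basis.shape[1] == 0 or np.max(np.abs(basis[p, :])) <= zero_tol:
            blocked.add(j)
    return frozenset(blocked)


def check_consistency(
    net: MetabolicNetwork,
    session: Optional[LPSession] = None,
    zero_tol: float = ZERO_TOL,
) -> ConsistencyResult:
    """Detect all blocked reactions with one LP plus one factorization.

    Blocked = (irreversible reactions outside the maximal irreversible
    support) ∪ (reversible reactions with identically-zero null-space
    row over the remainder).
    """
    session = session or LPSession()
    v = maximal_irreversible_support(net, session, zero_tol)
    support = v.support()
    blocked_irr = {
        j for j in np.flatnonzero(net.irreversible) if j not in support
    }
    retained = [j for j in range(net.n) if j not in blocked_irr]
    blocked_rev = blocked_reversibles(net, retained, zero_tol)
    blocked = frozenset(blocked_irr) | blocked_rev
    return ConsistencyResult(
        blocked=blocked,
        blocked_ids=sorted(net.reaction_ids[j] for j in blocked),
        witness_v=v,
        lp_count=session.count_lps(),
    )
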