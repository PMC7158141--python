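"""Slow, trusted brute-force oracles.

These deliberately avoid every shortcut the fast algorithms use: the
flux-variability oracle decides blockedness with two LPs per reaction,
and the minimal-subnetwork oracle enumerates core supersets by
increasing cardinality.  They exist to certify the fast paths on small
instances, never to be run at scale.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional

import numpy as np

from .config import ZERO_TOL
from .lp import LinearProgram, LPStatus, solve_lp
from .model import CoreSet, MetabolicNetwork, induced_subnetwork

__all__ = [
    "fva_blocked",
    "is_consistent_subnetwork",
    "minimal_subnetwork_bruteforce",
]

#: box bound making per-reaction optima finite; blockedness of the
#: homogeneous system is independent of its value
FVA_BOX = 1000.0


def _fva_extreme(net: MetabolicNetwork, j: int, sense: float,
                 box: float) -> float:
    """Optimum of (sense)*v_j over the boxed steady-state cone."""
    c = np.zeros(net.n)
    c[j] = sense
    lb = np.where(net.irreversible, 0.0, -box)
    ub = np.full(net.n, box)
    sol = solve_lp(LinearProgram(c, net.S, np.zeros(net.m), lb=lb, ub=ub))
    if sol.status is not LPStatus.OPTIMAL:
        raise RuntimeError(f"FVA LP for reaction {j} ended {sol.status}")
    return float(sol.primal[j])


def fva_blocked(
    net: MetabolicNetwork,
    tol: float = ZERO_TOL,
    box: float = FVA_BOX,
    early_exit: bool = False,
) -> frozenset[int]:
    """Blocked reactions by per-reaction flux maximization and
    minimization (2n LPs).  With ``early_exit`` the scan stops at the
    first blocked reaction (used by the enumeration oracle)."""
    blocked = set()
    for j in range(net.n):
        vmax = _fva_extreme(net, j, -1.0, box)
        if abs(vmax) > tol:
            continue
        if net.irreversible[j]:
            blocked.add(j)
        else:
            vmin = _fva_extreme(net, j, +1.0, box)
            if abs(vmin) <= tol:
                blocked.add(j)
        if blocked and early_exit:
            break
    return frozenset(blocked)


def is_consistent_subnetwork(net: MetabolicNetwork,
                             N: Iterable[int]) -> bool:
    """True iff the induced subnetwork has no blocked reaction (the
    empty subnetwork is vacuously consistent)."""
    N = sorted(set(N))
    if not N:
        return True
    return not fva_blocked(induced_subnetwork(net, N), early_exit=True)


def minimal_subnetwork_bruteforce(
    net: MetabolicNetwork,
    core: CoreSet,
    n_cap: int = 14,
) -> tuple[int, frozenset[int]]:
    """Exact minimum-size consistent superset of the core, by
    exhaustive enumeration in increasing cardinality (exponential;
    refuses networks larger than ``n_cap``)."""
    if net.n > n_cap:
        raise ValueError(
            f"brute force refused: n={net.n} exceeds cap {n_cap}"
        )
    core_set = frozenset(core.reaction_indices)
    others = sorted(frozenset(range(net.n)) - core_set)
    for extra in range(len(others) + 1):
        for combo in combinations(others, extra):
            candidate = core_set | set(combo)
            if is_consistent_subnetwork(net, candidate):
                return len(candidate), frozenset(candidate)
    # unreachable when the full network is consistent and contains core
    raise RuntimeError("no consistent superset of the core exists")
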