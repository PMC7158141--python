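"""Greedy extraction of a minimal flux-consistent subnetwork containing
a core reaction set.

Given a flux-consistent network and core reactions C, the goal is a
small subnetwork N ⊇ C in which no reaction is blocked (the exact
minimum is NP-hard).  The method is a two-phase LP relaxation:

1. **Sparse core-covering flux** — minimize the weighted l1 norm of the
   flux outside the core subject to steady state, flux >= 1 on
   irreversible core reactions and >= 0 on other irreversible
   reactions.  Its support (plus C) seeds N; every irreversible member
   of N is already certified active by this flux.
2. **Randomized dense witnesses** — the reversible members of N with
   zero seed flux (the unverified set B) are activated by repeatedly
   solving

       minimize  x' u_B + (1/σ) ω' w
       s.t.      S u = 0,  -1 <= u_B <= 1,  -w <= u_{R\\N} <= w,

   with x standard normal: random *soft* direction preferences replace
   the hard direction enumeration that slows sign-flipping approaches.
   Reactions with |u_j| > tol leave B; support recruited outside N
   joins N.  σ doubles whenever an iteration fails to halve |B|
   (larger σ relaxes the sparsity pressure so u can spread over B).

Optional refinements: an SVD null-space pass that harvests witnesses
for free before any randomized LP, a lossless full-coupling reduction
(see :mod:`coreprune.reduction`), and iterative re-runs of the whole
pipeline on its own output until the size stops shrinking.  A final
authoritative certification re-checks consistency of the induced
subnetwork and core containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space

from .config import FEASIBILITY_TOL, ZERO_TOL
from .consistency import check_consistency
from .lp import LinearProgram, LPSession, LPStatus
from .model import CoreSet, FluxVector, MetabolicNetwork, induced_subnetwork
from .reduction import couple_reduce, expand_flux, expand_solution

__all__ = [
    "ReconstructionOptions",
    "ReconstructionState",
    "ReconstructionResult",
    "CoreBlockedError",
    "IterationCapError",
    "sparse_core_flux",
    "nullspace_witnesses",
    "witness_step",
    "update_state",
    "sigma_update",
    "extract_subnetwork",
    "extract_subnetwork_iterative",
]


class CoreBlockedError(RuntimeError):
    """The core contains a reaction that cannot carry steady-state flux."""


class IterationCapError(RuntimeError):
    """The witness loop failed to empty B within the iteration cap."""


@dataclass
class ReconstructionOptions:
    """Tunable knobs of the extraction.

    ``weights`` is a positive cost per reaction (entries on core
    reactions are ignored — core membership is free); ``sigma0`` the
    initial sparsity/density trade-off σ > 0; the randomized witness
    loop is reproducible through ``rng_seed``.
    """

    weights: Optional[np.ndarray] = None
    sigma0: float = 1.0
    rng_seed: int = 0
    use_svd_init: bool = False
    use_coupling_reduction: bool = False
    shrink_iterate: bool = False
    max_witness_iters: Optional[int] = None
    tol: float = ZERO_TOL
    solver: str = "highs"
    bounded: bool = False

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if np.any(self.weights <= 0):
                raise ValueError("weights must be entrywise positive")


@dataclass
class ReconstructionState:
    """Evolving subnetwork N, unverified set B, and witness history."""

    N: set[int]
    B: set[int]
    witnesses: list[FluxVector]
    v0: FluxVector
    sigma: float
    lp_count: int = 0
    iteration: int = 0
    sigma_history: list[float] = field(default_factory=list)


@dataclass
class ReconstructionResult:
    N: frozenset[int]
    reaction_ids: list[str]
    certified: bool
    lp_count: int
    iterations: int
    sigma_history: list[float]
    v0: FluxVector
    witnesses: list[FluxVector]
    seed: int

    @property
    def size(self) -> int:
        return len(self.N)


# ---------------------------------------------------------------------
# phase 1: sparse core-covering flux
# ---------------------------------------------------------------------

def sparse_core_flux(
    net: MetabolicNetwork,
    core: CoreSet,
    weights: Optional[np.ndarray] = None,
    session: Optional[LPSession] = None,
    bounded: bool = False,
) -> FluxVector:
    """Minimum weighted-l1 steady-state flux through the core.

    minimize  ω' w   s.t.  S v = 0,  v_j >= 1 (irreversible core j),
    v_j >= 0 (irreversible non-core j),  -w <= v_{R\\C} <= w.

    Scaling the core fluxes to >= 1 keeps the problem homogeneous-free
    and pushes nonzero entries well above the zero tolerance.  An
    infeasible LP means an irreversible core reaction is blocked.
    """
    session = session or LPSession()
    if weights is None:
        weights = np.ones(net.n)
    n = net.n
    core_idx = set(core.reaction_indices)
    noncore = [j for j in range(n) if j not in core_idx]
    p = len(noncore)
    c = np.concatenate([np.zeros(n), np.asarray(weights)[noncore]])
    A_eq = sp.hstack([net.S, sp.csc_matrix((net.m, p))], format="csc")
    rows = np.arange(p)
    nz = np.array(noncore, dtype=int)
    # v_j - w_p <= 0 and -v_j - w_p <= 0
    A_ub = sp.coo_matrix(
        (np.concatenate([np.ones(p), -np.ones(p), -np.ones(p), -np.ones(p)]),
         (np.concatenate([rows, rows, p + rows, p + rows]),
          np.concatenate([nz, n + rows, nz, n + rows]))),
        shape=(2 * p, n + p),
    ).tocsc() if p else None
    b_ub = np.zeros(2 * p) if p else None
    lb = np.full(n + p, -np.inf)
    ub = np.full(n + p, np.inf)
    lb[n:] = 0.0
    for j in range(n):
        if net.irreversible[j]:
            lb[j] = 1.0 if j in core_idx else 0.0
    if bounded and net.bounds is not None:
        for j in range(n):
            lo, hi = net.bounds[j]
            lb[j] = max(lb[j], lo) if not (net.irreversible[j] and j in core_idx) \
                else max(min(1.0, 0.99 * hi), lo)
            ub[j] = min(ub[j], hi)
    sol = session.solve(
        LinearProgram(c, A_eq, np.zeros(net.m), A_ub, b_ub, lb, ub)
    )
    if sol.status is LPStatus.INFEASIBLE:
        raise CoreBlockedError(
            "core contains a blocked irreversible reaction "
            "(the sparse core-covering LP is infeasible)"
        )
    if sol.status is not LPStatus.OPTIMAL:
        raise RuntimeError(f"core-covering LP ended with status {sol.status}")
    return FluxVector(sol.primal[:n])


# ---------------------------------------------------------------------
# phase 2: witnesses
# ---------------------------------------------------------------------

def nullspace_witnesses(
    net: MetabolicNetwork,
    N: set[int] | frozenset[int],
    rank_tol: float = FEASIBILITY_TOL,
) -> list[FluxVector]:
    """Orthonormal null-space basis of the column-restricted S, each
    vector padded with zeros outside N — free witnesses that need no
    LP.  Empty when the restricted matrix has full column rank."""
    cols = sorted(N)
    if not cols:
        return []
    basis = null_space(net.S[:, cols].toarray(), rcond=rank_tol)
    out = []
    for q in range(basis.shape[1]):
        full = np.zeros(net.n)
        full[cols] = basis[:, q]
        out.append(FluxVector(full))
    return out


def witness_step(
    net: MetabolicNetwork,
    N: set[int] | frozenset[int],
    B: set[int] | frozenset[int],
    x: np.ndarray,
    sigma: float,
    weights: Optional[np.ndarray] = None,
    session: Optional[LPSession] = None,
) -> FluxVector:
    """One randomized dense-witness LP (see module docstring).

    ``x`` carries one standard-normal entry per member of B (sorted
    order).  Sign handling: the printed objective treats reversible
    directions softly through x; irreversible reactions *outside* N are
    additionally kept nonnegative so that newly recruited reactions
    enter forward-feasible.
    """
    if not B:
        raise ValueError("B must be nonempty")
    session = session or LPSession()
    if weights is None:
        weights = np.ones(net.n)
    n = net.n
    B_sorted = sorted(B)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(B_sorted):
        raise ValueError("x must have one entry per member of B")
    outside = [j for j in range(n) if j not in N]
    p = len(outside)
    c = np.zeros(n + p)
    c[B_sorted] = x
    c[n:] = np.asarray(weights)[outside] / sigma
    A_eq = sp.hstack([net.S, sp.csc_matrix((net.m, p))], format="csc")
    if p:
        rows = np.arange(p)
        oz = np.array(outside, dtype=int)
        A_ub = sp.coo_matrix(
            (np.concatenate([np.ones(p), -np.ones(p),
                             -np.ones(p), -np.ones(p)]),
             (np.concatenate([rows, rows, p + rows, p + rows]),
              np.concatenate([oz, n + rows, oz, n + rows]))),
            shape=(2 * p, n + p),
        ).tocsc()
        b_ub = np.zeros(2 * p)
    else:
        A_ub = b_ub = None
    lb = np.full(n + p, -np.inf)
    ub = np.full(n + p, np.inf)
    lb[n:] = 0.0
    for j in B_sorted:
        lb[j], ub[j] = -1.0, 1.0
    for j in outside:
        if net.irreversible[j]:
            lb[j] = 0.0
    sol = session.solve(
        LinearProgram(c, A_eq, np.zeros(net.m), A_ub, b_ub, lb, ub)
    )
    if sol.status is not LPStatus.OPTIMAL:
        # u = 0 is feasible, so only numeric trouble lands here
        raise RuntimeError(f"witness LP ended with status {sol.status}")
    return FluxVector(sol.primal[:n])


def update_state(state: ReconstructionState, u: FluxVector,
                 tol: float = ZERO_TOL) -> ReconstructionState:
    """Remove witnessed reactions from B, absorb new support into N."""
    supp = {int(j) for j in np.flatnonzero(np.abs(u.values) > tol)}
    state.B -= supp
    state.N |= supp
    state.witnesses.append(u)
    return state


def sigma_update(sigma: float, b_before: int, b_after: int) -> float:
    """Double σ iff the iteration failed to halve |B| (reduction by
    exactly half counts as sufficient progress)."""
    return 2.0 * sigma if b_after > b_before / 2 else sigma


def _targeted_witness(net, N, B, j, sigma, weights, session, tol):
    """Stagnation fallback: two sign-fixed LPs maximizing |u_j| within
    the witness feasible set (w boxed at 1000, tiny sparsity nudge)."""
    n = net.n
    outside = [q for q in range(n) if q not in N]
    p = len(outside)
    best: Optional[FluxVector] = None
    for sgn in (+1.0, -1.0):
        c = np.zeros(n + p)
        c[j] = -sgn
        c[n:] = 1e-6
        A_eq = sp.hstack([net.S, sp.csc_matrix((net.m, p))], format="csc")
        if p:
            rows = np.arange(p)
            oz = np.array(outside, dtype=int)
            A_ub = sp.coo_matrix(
                (np.concatenate([np.ones(p), -np.ones(p),
                                 -np.ones(p), -np.ones(p)]),
                 (np.concatenate([rows, rows, p + rows, p + rows]),
                  np.concatenate([oz, n + rows, oz, n + rows]))),
                shape=(2 * p, n + p),
            ).tocsc()
            b_ub = np.zeros(2 * p)
        else:
            A_ub = b_ub = None
        lb = np.full(n + p, -np.inf)
        ub = np.full(n + p, np.inf)
        lb[n:], ub[n:] = 0.0, 1000.0
        for q in B:
            lb[q], ub[q] = -1.0, 1.0
        for q in outside:
            if net.irreversible[q]:
                lb[q] = 0.0
        sol = session.solve(
            LinearProgram(c, A_eq, np.zeros(net.m), A_ub, b_ub, lb, ub)
        )
        if sol.status is LPStatus.OPTIMAL and abs(sol.primal[j]) > tol:
            best = FluxVector(sol.primal[:n])
            break
    return best


# ---------------------------------------------------------------------
# main pipeline
# ---------------------------------------------------------------------

def extract_subnetwork(
    net: MetabolicNetwork,
    core: CoreSet,
    options: Optional[ReconstructionOptions] = None,
) -> ReconstructionResult:
    """Run the full greedy extraction pipeline on a flux-consistent
    network; returns a certified subnetwork result.

    The LP count covers the extraction itself (core-covering LP plus
    witness iterations); the authoritative post-hoc certification is
    accounted separately.
    """
    options = options or ReconstructionOptions()
    core.validate_against(net)
    session = LPSession(solver=options.solver)
    rng = np.random.default_rng(options.rng_seed)
    tol = options.tol

    work_net, work_core = net, core
    weights = options.weights if options.weights is not None \
        else np.ones(net.n)
    rmap = None
    if options.use_coupling_reduction:
        work_net, work_core, weights, rmap = couple_reduce(net, core, weights)
        if rmap.dropped & set(core.reaction_indices):
            raise CoreBlockedError(
                "core contains a reaction proven blocked during coupling "
                "reduction"
            )

    v0 = sparse_core_flux(work_net, work_core, weights, session,
                          bounded=options.bounded)
    N = set(v0.support()) | set(work_core.reaction_indices)
    B = {j for j in N
         if not work_net.irreversible[j] and abs(v0.values[j]) <= tol}
    state = ReconstructionState(N=N, B=B, witnesses=[v0], v0=v0,
                                sigma=options.sigma0,
                                sigma_history=[options.sigma0])

    if options.use_svd_init and state.B:
        for u in nullspace_witnesses(work_net, state.N):
            update_state(state, u, tol)

    b0 = len(state.B)
    cap = options.max_witness_iters
    if cap is None:
        cap = int(20 + 2 * math.log2(max(b0, 1))) if b0 else 0
    stagnant = 0
    while state.B and state.iteration < cap:
        x = rng.standard_normal(len(state.B))
        u = witness_step(work_net, state.N, state.B, x, state.sigma,
                         weights, session)
        b_before = len(state.B)
        update_state(state, u, tol)
        b_after = len(state.B)
        state.sigma = sigma_update(state.sigma, b_before, b_after)
        state.sigma_history.append(state.sigma)
        state.iteration += 1
        stagnant = stagnant + 1 if b_after == b_before else 0
        if stagnant >= 3 and state.B:
            for j in sorted(state.B):
                if j not in state.B:  # witnessed by an earlier fallback u
                    continue
                u = _targeted_witness(work_net, state.N, state.B, j,
                                      state.sigma, weights, session, tol)
                if u is not None:
                    update_state(state, u, tol)
                else:
                    if j in work_core.reaction_indices:
                        raise CoreBlockedError(
                            f"core reaction {work_net.reaction_ids[j]!r} "
                            "cannot carry steady-state flux"
                        )
                    # provably inactive even with recruitment: drop it
                    state.B.discard(j)
                    state.N.discard(j)
            stagnant = 0
    if state.B:
        raise IterationCapError(
            f"{len(state.B)} reactions still unverified after "
            f"{state.iteration} witness iterations"
        )
    state.lp_count = session.count_lps()

    if rmap is not None:
        N_final = set(expand_solution(state.N, rmap))
        v0_full = FluxVector(expand_flux(state.v0.values, rmap))
    else:
        N_final = set(state.N)
        v0_full = state.v0

    certified = _certify(net, core, N_final)
    if not certified:
        # one repair pass: drop uncertified non-core stragglers
        blocked = _blocked_within(net, N_final)
        if blocked & set(core.reaction_indices):
            raise CoreBlockedError(
                "final verification found a blocked core reaction"
            )
        N_final -= blocked
        certified = _certify(net, core, N_final)

    return ReconstructionResult(
        N=frozenset(N_final),
        reaction_ids=sorted(net.reaction_ids[j] for j in N_final),
        certified=certified,
        lp_count=state.lp_count,
        iterations=state.iteration,
        sigma_history=state.sigma_history,
        v0=v0_full,
        witnesses=state.witnesses,
        seed=options.rng_seed,
    )


def _blocked_within(net: MetabolicNetwork, N: set[int]) -> set[int]:
    cols = sorted(N)
    res = check_consistency(induced_subnetwork(net, cols))
    return {cols[p] for p in res.blocked}


def _certify(net: MetabolicNetwork, core: CoreSet, N: set[int]) -> bool:
    if not set(core.reaction_indices) <= N:
        return False
    return not _blocked_within(net, N)


def extract_subnetwork_iterative(
    net: MetabolicNetwork,
    core: CoreSet,
    options: Optional[ReconstructionOptions] = None,
) -> ReconstructionResult:
    """Repeat the extraction with the previous output as the ambient
    network until the size no longer decreases; |N| is non-increasing
    across rounds.  The returned result indexes the original network
    and aggregates the LP count over all rounds."""
    options = options or ReconstructionOptions()
    ambient_idx = list(range(net.n))  # original indices of current ambient
    core_orig = set(core.reaction_indices)
    total_lps = 0
    result = None
    prev_size = None
    round_no = 0
    while True:
        ambient = induced_subnetwork(net, ambient_idx) \
            if len(ambient_idx) < net.n else net
        local_core = CoreSet(frozenset(
            p for p, j in enumerate(ambient_idx) if j in core_orig
        ))
        local_opts = ReconstructionOptions(
            weights=None if options.weights is None
            else options.weights[ambient_idx],
            sigma0=options.sigma0,
            rng_seed=options.rng_seed + round_no,
            use_svd_init=options.use_svd_init,
            use_coupling_reduction=options.use_coupling_reduction,
            max_witness_iters=options.max_witness_iters,
            tol=options.tol,
            solver=options.solver,
            bounded=options.bounded,
        )
        res = extract_subnetwork(ambient, local_core, local_opts)
        total_lps += res.lp_count
        N_orig = frozenset(ambient_idx[p] for p in res.N)
        v0_full = np.zeros(net.n)
        v0_full[ambient_idx] = res.v0.values
        res.v0 = FluxVector(v0_full)
        result = ReconstructionResult(
            N=N_orig,
            reaction_ids=sorted(net.reaction_ids[j] for j in N_orig),
            certified=res.certified,
            lp_count=total_lps,
            iterations=res.iterations,
            sigma_history=res.sigma_history,
            v0=res.v0,
            witnesses=res.witnesses,
            seed=options.rng_seed,
        )
        if prev_size is not None and len(N_orig) >= prev_size:
            return result
        prev_size = len(N_orig)
        ambient_idx = sorted(N_orig)
        round_no += 1
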