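"""Lossless merging of fully coupled reaction pairs.

When a metabolite appears in exactly two reactions k and l, steady
state forces their fluxes into the fixed ratio v_l = λ v_k with
λ = -S_ik / S_il.  The pair can then be merged into a single column
``S_k + λ S_l`` and the metabolite row dropped without changing the
steady-state flux space — a cheap preprocessing that shrinks the LPs.
Sign bookkeeping: with λ < 0 the constituents' irreversibility
constraints may restrict the merged flux to t <= 0 (column negated and
made irreversible) or to t = 0 (the pair is provably blocked and is
dropped, recorded in the map).  Merging runs to a fixpoint and is fully
invertible through :func:`expand_solution` / :func:`expand_flux`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp

from .model import CoreSet, MetabolicNetwork

__all__ = ["ReductionMap", "couple_reduce", "expand_solution", "expand_flux"]

# feasible sign set of a merged flux variable t
_FREE, _POS, _ZERO = "free", "pos", "zero"


@dataclass
class ReductionMap:
    """Bookkeeping to undo a coupling reduction.

    ``composition[p]`` lists ``(original_index, multiplier)`` pairs for
    reduced column p: a reduced flux t expands to ``multiplier * t`` on
    each constituent.  ``dropped`` are original reactions proven blocked
    during merging (empty feasible sign set); they never reappear.
    """

    composition: list[list[tuple[int, float]]]
    dropped: frozenset[int]
    n_original: int
    merge_log: list[tuple[str, str, str, float]] = field(default_factory=list)


def couple_reduce(
    net: MetabolicNetwork,
    core: CoreSet,
    weights: Optional[np.ndarray] = None,
) -> tuple[MetabolicNetwork, CoreSet, np.ndarray, ReductionMap]:
    """Merge fully coupled pairs to a fixpoint.

    The merged reaction is in the reduced core iff any constituent was;
    its weight is the sum of its non-core constituents' weights.
    """
    if weights is None:
        weights = np.ones(net.n)
    weights = np.asarray(weights, dtype=float)

    S = net.S.toarray()
    row_ids = list(net.metabolite_ids)
    active_rows = list(range(net.m))
    cols: list[np.ndarray] = [S[:, j].copy() for j in range(net.n)]
    combo: list[list[tuple[int, float]]] = [[(j, 1.0)] for j in range(net.n)]
    sign: list[str] = [_POS if net.irreversible[j] else _FREE
                       for j in range(net.n)]
    ids: list[str] = list(net.reaction_ids)
    active_cols = set(range(net.n))
    dropped: set[int] = set()
    unmergeable: set[int] = set()
    log: list[tuple[str, str, str, float]] = []

    def nonzero_cols_of_row(i: int) -> list[int]:
        return [j for j in active_cols if abs(cols[j][i]) > 1e-12]

    changed = True
    while changed:
        changed = False
        for i in list(active_rows):
            if i in unmergeable:
                continue
            adj = nonzero_cols_of_row(i)
            if len(adj) != 2:
                continue
            k, l = adj
            lam = -cols[k][i] / cols[l][i]
            merged_col = cols[k] + lam * cols[l]
            merged_col[i] = 0.0  # exact by construction
            if np.max(np.abs(merged_col)) <= 1e-12:
                unmergeable.add(i)  # merging would create an empty column
                continue
            # combine feasible sign sets of t (v_k = t, v_l = lam * t)
            s_k, s_l = sign[k], sign[l]
            s_l_t = s_l if (lam > 0 or s_l == _FREE) else "neg"
            if s_k == _FREE:
                s = s_l_t
            elif s_l_t == _FREE or s_l_t == s_k:
                s = s_k
            else:  # pos ∩ neg
                s = _ZERO
            log.append((ids[k], ids[l], row_ids[i], lam))
            new_combo = [(orig, mult) for orig, mult in combo[k]]
            new_combo += [(orig, lam * mult) for orig, mult in combo[l]]
            if s == _ZERO:
                dropped.update(orig for orig, _ in new_combo)
                active_cols.discard(k)
                active_cols.discard(l)
                active_rows.remove(i)
                changed = True
                continue
            if s == "neg":
                merged_col = -merged_col
                new_combo = [(o, -m) for o, m in new_combo]
                s = _POS
            cols[k] = merged_col
            combo[k] = new_combo
            sign[k] = s
            ids[k] = ids[k] + "+" + ids[l]
            active_cols.discard(l)
            active_rows.remove(i)
            changed = True

    keep = sorted(active_cols)
    rows = sorted(set(active_rows))
    S_red = np.column_stack([cols[j] for j in keep])[rows, :] if keep else \
        np.zeros((len(rows), 0))
    core_orig = set(core.reaction_indices)
    red_core = frozenset(
        p for p, j in enumerate(keep)
        if any(orig in core_orig for orig, _ in combo[j])
    )
    red_weights = np.array([
        sum(weights[orig] for orig, _ in combo[j] if orig not in core_orig)
        or 1.0
        for j in keep
    ])
    reduced = MetabolicNetwork(
        metabolite_ids=[row_ids[i] for i in rows],
        reaction_ids=[ids[j] for j in keep],
        S=sp.csc_matrix(S_red),
        irreversible=np.array([sign[j] == _POS for j in keep]),
    )
    rmap = ReductionMap(
        composition=[combo[j] for j in keep],
        dropped=frozenset(dropped),
        n_original=net.n,
        merge_log=log,
    )
    return reduced, CoreSet(red_core), red_weights, rmap


def expand_solution(n_reduced: Iterable[int], rmap: ReductionMap) -> frozenset[int]:
    """Map a reduced-net reaction index set back to original indices."""
    out: set[int] = set()
    for p in n_reduced:
        out.update(orig for orig, _ in rmap.composition[p])
    return frozenset(out)


def expand_flux(values_reduced: np.ndarray, rmap: ReductionMap) -> np.ndarray:
    """Expand a reduced-net flux with the recorded multipliers; a
    steady-state flux of the reduced net maps to one of the original."""
    values_reduced = np.asarray(values_reduced, dtype=float).ravel()
    out = np.zeros(rmap.n_original)
    for p, parts in enumerate(rmap.composition):
        for orig, mult in parts:
            out[orig] += mult * values_reduced[p]
    return out
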