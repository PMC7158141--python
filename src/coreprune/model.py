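"""Core domain types for constraint-based metabolic networks.

A metabolic network is an m x n stoichiometric matrix ``S`` (rows are
metabolites, columns are reactions, reactants negative, products
positive) together with a per-reaction irreversibility flag.  A
steady-state flux distribution is a vector ``v`` with ``S v = 0`` and
``v_j >= 0`` for every irreversible reaction j.  Everything else in the
package (blocked-reaction detection, subnetwork extraction, graph
preprocessing) is defined in terms of these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .config import FEASIBILITY_TOL, ZERO_TOL

__all__ = [
    "MetabolicNetwork",
    "CoreSet",
    "FluxVector",
    "ValidationError",
    "boundary_reactions",
    "split_reversible",
    "induced_subnetwork",
]


class ValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, empty
    column, inconsistent bounds...)."""


@dataclass
class MetabolicNetwork:
    """A stoichiometric model: sparse ``S``, identifiers, and
    irreversibility flags.

    Parameters
    ----------
    metabolite_ids:
        Unique metabolite identifiers; length m, one per row of ``S``.
    reaction_ids:
        Unique reaction identifiers; length n, one per column of ``S``.
    S:
        m x n stoichiometric coefficient matrix (any scipy-sparse or
        dense array; stored as CSC).
    irreversible:
        Boolean flag per reaction; ``True`` means the reaction may only
        carry nonnegative flux.
    bounds:
        Optional (n, 2) array of per-reaction lower/upper flux bounds.
        Only the sign structure matters for consistency analysis; bounds
        participate in the optional bounded reconstruction mode.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    irreversible: np.ndarray
    bounds: Optional[np.ndarray] = None
    #: rows that became empty after a column restriction (kept, flagged)
    empty_metabolite_rows: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.irreversible = np.asarray(self.irreversible, dtype=bool)
        self.metabolite_ids = list(self.metabolite_ids)
        self.reaction_ids = list(self.reaction_ids)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m:
            raise ValidationError(
                f"{len(self.metabolite_ids)} metabolite ids for {m} rows"
            )
        if len(self.reaction_ids) != n:
            raise ValidationError(
                f"{len(self.reaction_ids)} reaction ids for {n} columns"
            )
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValidationError(f"duplicate {name} id {dup!r}")
        if self.irreversible.shape != (n,):
            raise ValidationError("irreversible flag vector has wrong length")
        counts = np.diff(self.S.indptr)
        if n and counts.min() == 0:
            j = int(np.argmin(counts))
            raise ValidationError(
                f"reaction {self.reaction_ids[j]!r} has an all-zero column"
            )
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float).reshape(n, 2)
            if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
                raise ValidationError("lower bound exceeds upper bound")
            if np.any(self.irreversible & (self.bounds[:, 0] < 0)):
                raise ValidationError(
                    "irreversible reaction with negative lower bound"
                )

    # -- conveniences -------------------------------------------------
    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def reversible(self) -> np.ndarray:
        return ~self.irreversible

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def indices_of(self, rids: Iterable[str]) -> list[int]:
        return [self.reaction_index(r) for r in rids]


@dataclass
class CoreSet:
    """A set of reaction column indices that an extracted subnetwork
    must contain and keep unblocked."""

    reaction_indices: frozenset[int]

    def __post_init__(self) -> None:
        self.reaction_indices = frozenset(int(i) for i in self.reaction_indices)

    @classmethod
    def from_ids(cls, net: MetabolicNetwork, rids: Iterable[str]) -> "CoreSet":
        return cls(frozenset(net.indices_of(rids)))

    def validate_against(self, net: MetabolicNetwork) -> None:
        bad = [i for i in self.reaction_indices if not 0 <= i < net.n]
        if bad:
            raise ValidationError(f"core indices out of range: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.reaction_indices)

    def __iter__(self):
        return iter(sorted(self.reaction_indices))


@dataclass
class FluxVector:
    """A candidate flux distribution with a tolerance-based support."""

    values: np.ndarray
    zero_tol: float = ZERO_TOL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.zero_tol < 0:
            raise ValidationError("zero_tol must be nonnegative")

    def support(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(np.abs(self.values) > self.zero_tol))

    def is_steady_state(self, net: MetabolicNetwork,
                        feas_tol: float = FEASIBILITY_TOL) -> bool:
        """True when ``S v`` vanishes and irreversible fluxes are
        nonnegative up to tolerance."""
        if self.values.shape != (net.n,):
            return False
        residual = np.abs(net.S @ self.values)
        if residual.size and residual.max() > max(feas_tol, 1e-9):
            return False
        irr = net.irreversible
        return not np.any(self.values[irr] < -self.zero_tol)


# ---------------------------------------------------------------------
# structural helpers
# ---------------------------------------------------------------------

def boundary_reactions(net: MetabolicNetwork) -> frozenset[int]:
    """Reactions whose stoichiometric column is entrywise >= 0 or
    entrywise <= 0 — exchanges with the environment."""
    out = set()
    S = net.S
    for j in range(net.n):
        col = S.data[S.indptr[j]:S.indptr[j + 1]]
        if np.all(col >= 0) or np.all(col <= 0):
            out.add(j)
    return frozenset(out)


def internal_reactions(net: MetabolicNetwork) -> frozenset[int]:
    return frozenset(range(net.n)) - boundary_reactions(net)


def split_reversible(
    net: MetabolicNetwork,
) -> tuple[MetabolicNetwork, list[tuple[int, int]]]:
    """Replace each reversible reaction by a forward and a reverse
    irreversible copy.

    Returns the split network and an index map: entry k of the map is
    ``(j, d)`` with j the original column and d = +1 (forward, column
    ``S_j``) or -1 (reverse, column ``-S_j``).  Irreversible reactions
    pass through with d = +1.
    """
    cols = []
    ids = []
    index_map: list[tuple[int, int]] = []
    for j in range(net.n):
        col = net.S[:, [j]]
        cols.append(col)
        ids.append(net.reaction_ids[j])
        index_map.append((j, +1))
        if not net.irreversible[j]:
            cols.append(-col)
            ids.append(net.reaction_ids[j] + "__rev")
            index_map.append((j, -1))
    if cols:
        S = sp.hstack(cols, format="csc")
    else:
        S = sp.csc_matrix((net.m, 0))
    split = MetabolicNetwork(
        metabolite_ids=net.metabolite_ids,
        reaction_ids=ids,
        S=S,
        irreversible=np.ones(len(ids), dtype=bool),
    )
    return split, index_map


def induced_subnetwork(
    net: MetabolicNetwork,
    keep: Iterable[int],
    drop_empty_rows: bool = False,
) -> MetabolicNetwork:
    """Restrict the network to the given reaction columns.

    Metabolite rows that become all-zero are retained (and flagged) by
    default; pass ``drop_empty_rows=True`` to remove them.
    """
    keep = sorted(set(int(k) for k in keep))
    if any(k < 0 or k >= net.n for k in keep):
        raise ValidationError("keep set contains out-of-range indices")
    S = net.S[:, keep].tocsc()
    irr = net.irreversible[keep]
    ids = [net.reaction_ids[k] for k in keep]
    bounds = net.bounds[keep] if net.bounds is not None else None
    row_counts = np.asarray((S != 0).sum(axis=1)).ravel()
    empty = np.flatnonzero(row_counts == 0)
    if drop_empty_rows and empty.size:
        keep_rows = np.flatnonzero(row_counts > 0)
        S = S[keep_rows, :].tocsc()
        mids = [net.metabolite_ids[i] for i in keep_rows]
        empty_flag: frozenset[int] = frozenset()
    else:
        mids = net.metabolite_ids
        empty_flag = frozenset(int(i) for i in empty)
    sub = MetabolicNetwork.__new__(MetabolicNetwork)
    # bypass the nonzero-column check only for the degenerate 0-column case
    sub.metabolite_ids = list(mids)
    sub.reaction_ids = ids
    sub.S = sp.csc_matrix(S, dtype=float)
    sub.irreversible = np.asarray(irr, dtype=bool)
    sub.bounds = bounds
    sub.empty_metabolite_rows = empty_flag
    if ids:
        sub.validate()
    return sub
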