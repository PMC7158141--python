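"""Stoichiometric consistency and boundary internalization.

A network is *stoichiometrically consistent* when a strictly positive
molecular-mass vector ``w`` exists with ``w' S_I = 0`` on the internal
reactions — every internal reaction conserves mass.  Feasibility of
``{S_I' w = 0, w >= 1}`` is decided by a single LP (the scale of ``w``
is arbitrary, so w >= 1 loses no generality).

Boundary reactions (entrywise one-signed columns) are *internalized* by
appending a fictitious extracellular metabolite: the augmented matrix

    S' = [ W S ; -w' S ]

(with W = diag(w)) has column sums exactly zero, every boundary column
gains a fictitious-row entry of the opposite sign, and internal columns
do not involve the new metabolite.  Since the added row is a linear
combination of the others, the steady-state flux set is unchanged.  The
*sign* structure of S' needs no ``w`` at all, which is what the graph
preprocessing consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .config import FEASIBILITY_TOL
from .lp import LinearProgram, LPSession, LPStatus
from .model import MetabolicNetwork, boundary_reactions

__all__ = [
    "StoichiometricAugmentation",
    "stoichiometric_consistency",
    "augment_with_fictitious_metabolite",
]


@dataclass
class StoichiometricAugmentation:
    """Internal/boundary split plus the augmented sign (and, when a mass
    vector is known, numeric) stoichiometry with a fictitious
    extracellular metabolite in the last row."""

    internal_reactions: frozenset[int]
    boundary_reactions: frozenset[int]
    #: (m+1) x n matrix with entries in {-1, 0, +1}
    sign_matrix: sp.csc_matrix
    mass_vector: Optional[np.ndarray] = None
    #: numeric S' = [W S; -w' S]; present only with a mass vector
    S_aug: Optional[sp.csc_matrix] = None

    @property
    def fictitious_row(self) -> int:
        return self.sign_matrix.shape[0] - 1


def stoichiometric_consistency(
    net: MetabolicNetwork,
    session: Optional[LPSession] = None,
) -> tuple[bool, Optional[np.ndarray]]:
    """Decide mass-conservation feasibility of the internal part.

    Solves  minimize 1'w  s.t.  S_I' w = 0,  w >= 1  (one LP).  Returns
    ``(True, w)`` when feasible and ``(False, None)`` otherwise; the
    scale of ``w`` is arbitrary.  Unboundedness is impossible (the
    objective is at least m).
    """
    session = session or LPSession()
    internal = sorted(frozenset(range(net.n)) - boundary_reactions(net))
    if not internal:
        return True, np.ones(net.m)
    A_eq = net.S[:, internal].T.tocsc()
    lp = LinearProgram(
        objective=np.ones(net.m),
        A_eq=A_eq,
        b_eq=np.zeros(len(internal)),
        lb=np.ones(net.m),
    )
    sol = session.solve(lp)
    if sol.status is LPStatus.OPTIMAL:
        return True, sol.primal
    if sol.status is LPStatus.INFEASIBLE:
        return False, None
    raise RuntimeError(f"mass-vector LP ended with status {sol.status}")


def augment_with_fictitious_metabolite(
    net: MetabolicNetwork,
    mass_vector: Optional[np.ndarray] = None,
) -> StoichiometricAugmentation:
    """Internalize boundary reactions via a fictitious metabolite.

    The sign structure is always built without ``w``: internal columns
    get 0 in the fictitious row; an entrywise-nonnegative boundary
    column gets -1, an entrywise-nonpositive one +1 (the opposite sign,
    so the column acquires both signs).  When ``mass_vector`` is given,
    the numeric ``S'`` is also materialized with its last row computed
    as minus the column sums of ``W S``, which makes ``1' S' = 0`` hold
    to the last bit.
    """
    bnd = boundary_reactions(net)
    internal = frozenset(range(net.n)) - bnd
    signs = net.S.sign().tolil()
    fict = np.zeros(net.n)
    for j in bnd:
        col = net.S.data[net.S.indptr[j]:net.S.indptr[j + 1]]
        fict[j] = -1.0 if np.all(col >= 0) else 1.0
    sign_matrix = sp.vstack(
        [signs.tocsc(), sp.csc_matrix(fict)], format="csc"
    )

    S_aug = None
    if mass_vector is not None:
        w = np.asarray(mass_vector, dtype=float).ravel()
        if w.shape != (net.m,) or np.any(w <= 0):
            raise ValueError("mass vector must be strictly positive, length m")
        WS = sp.diags(w) @ net.S
        last = -np.asarray(WS.sum(axis=0)).ravel()
        S_aug = sp.vstack([WS.tocsc(), sp.csc_matrix(last)], format="csc")

    return StoichiometricAugmentation(
        internal_reactions=internal,
        boundary_reactions=bnd,
        sign_matrix=sign_matrix,
        mass_vector=None if mass_vector is None else np.asarray(mass_vector,
                                                                dtype=float),
        S_aug=S_aug,
    )
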