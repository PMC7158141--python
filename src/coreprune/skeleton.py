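"""Metabolite-level skeleton digraph and SCC-partition preprocessing.

After internalizing boundary reactions (fictitious metabolite, column
sums zero) and splitting reversible reactions, each reaction hyperarc
breaks into the complete bipartite set of reactant->product arcs
``f(R_k) = {(M_i, M_j) : S'_ik < 0, S'_jk > 0}``.  With column sums
zero the stoichiometry factorizes exactly as ``S' = ∂ F`` where ``∂``
is the vertex-arc incidence matrix of the skeleton digraph and

    F[l, k] = -S'_ik * S'_jk / C_k,   C_k = (1/2) * sum_l |S'_lk|,

for arc ``A_l = (M_i, M_j)`` in ``f(R_k)``.  For any steady-state flux
``v``, ``F v`` is a circulation (``∂ F v = S' v = 0``), so every arc
carrying flow lies on a directed cycle; in particular all arcs of an
active reaction sit inside one strongly connected component of the
digraph.  A reaction whose arcs straddle SCCs is therefore blocked —
a sound (not complete) graph-theoretic pre-filter that partitions the
network into SCC-induced pieces which can be checked independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .config import ZERO_TOL
from .consistency import ConsistencyResult, check_consistency
from .lp import LPSession
from .model import (FluxVector, MetabolicNetwork, induced_subnetwork,
                    split_reversible)
from .stoichiometry import (StoichiometricAugmentation,
                            augment_with_fictitious_metabolite)

__all__ = [
    "SkeletonDigraph",
    "skeleton_digraph",
    "scc_partition",
    "check_consistency_partitioned",
]


@dataclass
class SkeletonDigraph:
    """Skeleton digraph with arc bookkeeping.

    ``vertices`` are metabolite row indices of the augmented matrix
    (the last one is the fictitious extracellular metabolite when any
    boundary reaction exists).  ``arc_of_reaction[k]`` lists the arc
    ids of ``f(R_k)``.  ``incidence`` (∂) and ``arc_flow`` (F) are
    built numerically whenever the augmentation carries a numeric S'.
    """

    n_vertices: int
    arcs: list[tuple[int, int]]
    arc_of_reaction: list[list[int]]
    incidence: Optional[sp.csc_matrix] = None
    arc_flow: Optional[sp.csc_matrix] = None

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.arcs)
        return g

    def arcs_of_support(self, support) -> set[tuple[int, int]]:
        """f̃ of a reaction subset: union of the per-reaction arc sets."""
        out: set[tuple[int, int]] = set()
        for k in support:
            out.update(self.arcs[a] for a in self.arc_of_reaction[k])
        return out


def skeleton_digraph(aug: StoichiometricAugmentation) -> SkeletonDigraph:
    """Build the skeleton digraph from an augmentation of an
    all-irreversible (already split) network.

    Arc (M_i, M_j) exists iff some column k has S'_ik < 0 and
    S'_jk > 0.  When numeric S' is available, ∂ and F are materialized;
    the identity S' = ∂ F then holds to numerical precision.
    """
    signs = aug.sign_matrix.tocsc()
    n_vert, n_rxn = signs.shape
    arc_index: dict[tuple[int, int], int] = {}
    arcs: list[tuple[int, int]] = []
    arc_of_reaction: list[list[int]] = []
    for k in range(n_rxn):
        col = signs[:, [k]].tocoo()
        neg = [i for i, v in zip(col.row, col.data) if v < 0]
        pos = [i for i, v in zip(col.row, col.data) if v > 0]
        mine = []
        for i in neg:
            for j in pos:
                key = (int(i), int(j))
                if key not in arc_index:
                    arc_index[key] = len(arcs)
                    arcs.append(key)
                mine.append(arc_index[key])
        arc_of_reaction.append(mine)

    incidence = arc_flow = None
    if aug.S_aug is not None:
        S = aug.S_aug.tocsc()
        a = len(arcs)
        inc = sp.lil_matrix((n_vert, a))
        for l, (i, j) in enumerate(arcs):
            inc[i, l] = -1.0
            inc[j, l] = 1.0
        F = sp.lil_matrix((a, n_rxn))
        for k in range(n_rxn):
            col = S[:, [k]].toarray().ravel()
            ck = 0.5 * np.abs(col).sum()
            if ck == 0:
                continue
            for l in arc_of_reaction[k]:
                i, j = arcs[l]
                F[l, k] = -col[i] * col[j] / ck
        incidence, arc_flow = inc.tocsc(), F.tocsc()

    return SkeletonDigraph(n_vert, arcs, arc_of_reaction, incidence, arc_flow)


def scc_partition(
    net: MetabolicNetwork,
    mass_vector: Optional[np.ndarray] = None,
) -> tuple[frozenset[int], list[list[int]]]:
    """Graph-theoretic pre-filter for blocked reactions.

    Splits reversible reactions, internalizes boundaries (sign-only
    unless a mass vector is supplied), builds the skeleton digraph, and
    partitions it into strongly connected components.  A split reaction
    is retained iff all its arcs lie within one SCC — equivalently, all
    metabolites it touches (fictitious included) share an SCC; an
    original reversible reaction is retained iff either direction is.

    Returns ``(blocked_by_graph, components)`` where components groups
    the retained original reactions by SCC.  The filter is sound
    (``blocked_by_graph`` is a subset of the true blocked set) but not
    complete; the LP-based checker finds the rest.
    """
    split, index_map = split_reversible(net)
    aug = augment_with_fictitious_metabolite(split, mass_vector)
    skel = skeleton_digraph(aug)
    g = skel.graph()
    comp_of = {}
    for cid, comp in enumerate(nx.strongly_connected_components(g)):
        for v in comp:
            comp_of[v] = cid

    signs = aug.sign_matrix.tocsc()
    retained_comp: dict[int, int] = {}
    for k, (j, _direction) in enumerate(index_map):
        if j in retained_comp:
            continue
        touched = signs[:, [k]].tocoo().row
        comps = {comp_of[i] for i in touched}
        if len(comps) == 1:
            retained_comp[j] = comps.pop()

    blocked = frozenset(range(net.n)) - retained_comp.keys()
    groups: dict[int, list[int]] = {}
    for j, cid in retained_comp.items():
        groups.setdefault(cid, []).append(j)
    components = [sorted(v) for _, v in sorted(groups.items())]
    return blocked, components


def check_consistency_partitioned(
    net: MetabolicNetwork,
    session: Optional[LPSession] = None,
    zero_tol: float = ZERO_TOL,
) -> ConsistencyResult:
    """SCC pre-filter followed by the LP checker on each component.

    The union of the graph-blocked set and the per-component blocked
    sets equals the plain checker's blocked set.
    """
    session = session or LPSession()
    blocked_by_graph, components = scc_partition(net)
    blocked = set(blocked_by_graph)
    witness = np.zeros(net.n)
    for comp in components:
        sub = induced_subnetwork(net, comp)
        res = check_consistency(sub, session, zero_tol)
        blocked.update(comp[p] for p in res.blocked)
        witness[comp] += res.witness_v.values
    return ConsistencyResult(
        blocked=frozenset(blocked),
        blocked_ids=sorted(net.reaction_ids[j] for j in blocked),
        witness_v=FluxVector(witness, zero_tol),
        lp_count=session.count_lps(),
        components=components,
    )
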