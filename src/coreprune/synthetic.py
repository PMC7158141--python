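"""Deterministic synthetic networks: hand-built fixtures and a seeded
random generator.

The generator emulates the gross topology of genome-scale models at
desk scale: parallel uptake→chain→secretion pathways, random
cross-links between pathways, and planted dead-end branches whose
reactions are blocked by construction (their terminal metabolite has a
single adjacent reaction, so its balance forces zero flux in either
direction).  All reactions are mass balanced with unit coefficients, so
the internal part is stoichiometrically consistent with w = 1; a flag
introduces a non-conserving coefficient for negative tests.
Reversibility is assigned by seeded draws on non-exchange reactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .model import CoreSet, MetabolicNetwork

__all__ = [
    "GeneratorSpec",
    "make_network",
    "generate_network",
    "random_core",
    "disjoint_union",
    "linear_chain",
    "dead_end_chain",
    "irreversible_two_cycle",
    "diamond",
    "mass_inconsistent_pair",
    "reversible_two_cycle",
    "two_cycles_with_bridge",
]


def make_network(
    metabolites: list[str],
    reactions: list[tuple[str, dict[str, float], bool]],
) -> MetabolicNetwork:
    """Build a network from ``(id, {metabolite: coeff}, irreversible)``
    triples; reactants carry negative coefficients."""
    midx = {m: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    rids, irrev = [], []
    for j, (rid, stoich, irr) in enumerate(reactions):
        rids.append(rid)
        irrev.append(irr)
        for met, coeff in stoich.items():
            rows.append(midx[met]); cols.append(j); vals.append(float(coeff))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(rids))
    )
    return MetabolicNetwork(metabolites, rids, S, np.array(irrev))


# ---------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------

def linear_chain() -> MetabolicNetwork:
    """∅→A→B→∅, all irreversible; fully consistent."""
    return make_network(
        ["A", "B"],
        [("E1", {"A": 1}, True),
         ("R1", {"A": -1, "B": 1}, True),
         ("E2", {"B": -1}, True)],
    )


def dead_end_chain() -> MetabolicNetwork:
    """∅→A→B with B unconsumed; both reactions blocked."""
    return make_network(
        ["A", "B"],
        [("E1", {"A": 1}, True),
         ("R1", {"A": -1, "B": 1}, True)],
    )


def irreversible_two_cycle() -> MetabolicNetwork:
    """A→B→A irreversible; the internal cycle carries flux."""
    return make_network(
        ["A", "B"],
        [("R1", {"A": -1, "B": 1}, True),
         ("R2", {"B": -1, "A": 1}, True)],
    )


def diamond() -> MetabolicNetwork:
    """∅→A; A→B and A→C; B→D and C→D; D→∅ — two parallel routes."""
    return make_network(
        ["A", "B", "C", "D"],
        [("E1", {"A": 1}, True),
         ("R1", {"A": -1, "B": 1}, True),
         ("R2", {"A": -1, "C": 1}, True),
         ("R3", {"B": -1, "D": 1}, True),
         ("R4", {"C": -1, "D": 1}, True),
         ("E2", {"D": -1}, True)],
    )


def mass_inconsistent_pair() -> MetabolicNetwork:
    """Internal A→B and B→2A: mass conservation forces w = 0, so no
    strictly positive mass vector exists."""
    return make_network(
        ["A", "B"],
        [("R1", {"A": -1, "B": 1}, True),
         ("R2", {"B": -1, "A": 2}, True)],
    )


def reversible_two_cycle() -> MetabolicNetwork:
    """A↔B through two reversible reactions; both unblocked."""
    return make_network(
        ["A", "B"],
        [("R1", {"A": -1, "B": 1}, False),
         ("R2", {"B": -1, "A": 1}, False)],
    )


def two_cycles_with_bridge() -> MetabolicNetwork:
    """Two disjoint irreversible 2-cycles joined by a one-way bridge;
    the bridge is blocked (nothing returns the mass it moves)."""
    return make_network(
        ["A1", "B1", "A2", "B2"],
        [("C1a", {"A1": -1, "B1": 1}, True),
         ("C1b", {"B1": -1, "A1": 1}, True),
         ("C2a", {"A2": -1, "B2": 1}, True),
         ("C2b", {"B2": -1, "A2": 1}, True),
         ("BR", {"B1": -1, "A2": 1}, True)],
    )


def disjoint_union(a: MetabolicNetwork, b: MetabolicNetwork,
                   suffix: str = "'") -> MetabolicNetwork:
    """Block-diagonal union; b's identifiers get ``suffix`` on clash."""
    b_mids = [m + suffix if m in set(a.metabolite_ids) else m
              for m in b.metabolite_ids]
    b_rids = [r + suffix if r in set(a.reaction_ids) else r
              for r in b.reaction_ids]
    S = sp.block_diag([a.S, b.S], format="csc")
    return MetabolicNetwork(
        a.metabolite_ids + b_mids,
        a.reaction_ids + b_rids,
        S,
        np.concatenate([a.irreversible, b.irreversible]),
    )


# ---------------------------------------------------------------------
# seeded generator
# ---------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Parameters of the synthetic pathway generator.

    ``n_pathways`` parallel source→sink chains of ``pathway_length``
    internal conversion steps, ``n_cross_links`` random one-way links
    between distinct pathways, ``n_planted_deadends`` branches to fresh
    terminal metabolites (ground-truth blocked), and every non-exchange
    reaction made reversible with probability ``reversible_fraction``.
    """

    n_pathways: int = 3
    pathway_length: int = 4
    n_cross_links: int = 2
    n_planted_deadends: int = 2
    reversible_fraction: float = 0.3
    rng_seed: int = 0
    unit_coefficients: bool = True

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.pathway_length < 1:
            raise ValueError("need at least one pathway of length >= 1")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")


def generate_network(spec: GeneratorSpec) -> tuple[MetabolicNetwork, dict]:
    """Deterministically generate a network from the spec.

    Returns the network and a ground-truth dictionary with the planted
    dead-end reaction ids (blocked by construction; cross-link-induced
    blocking, if any, is left to the flux-variability oracle to
    certify).
    """
    rng = np.random.default_rng(spec.rng_seed)
    mets: list[str] = []
    rxns: list[tuple[str, dict[str, float], bool]] = []
    internal_mets: list[str] = []

    for p in range(spec.n_pathways):
        chain = [f"m{p}_{i}" for i in range(spec.pathway_length + 1)]
        mets.extend(chain)
        internal_mets.extend(chain)
        rxns.append((f"EX{p}_in", {chain[0]: 1}, True))
        for i in range(spec.pathway_length):
            rxns.append((f"P{p}_{i}", {chain[i]: -1, chain[i + 1]: 1}, True))
        rxns.append((f"EX{p}_out", {chain[-1]: -1}, True))

    for c in range(spec.n_cross_links):
        if spec.n_pathways < 2:
            break
        p1, p2 = rng.choice(spec.n_pathways, size=2, replace=False)
        i1 = int(rng.integers(0, spec.pathway_length + 1))
        i2 = int(rng.integers(0, spec.pathway_length + 1))
        rxns.append((f"X{c}", {f"m{p1}_{i1}": -1, f"m{p2}_{i2}": 1}, True))

    planted: list[str] = []
    for d in range(spec.n_planted_deadends):
        src = internal_mets[int(rng.integers(0, len(internal_mets)))]
        dead = f"dead{d}"
        mets.append(dead)
        rxns.append((f"D{d}", {src: -1, dead: 1}, True))
        planted.append(f"D{d}")

    if not spec.unit_coefficients and rxns:
        # break mass conservation on one internal conversion
        for idx, (rid, st, irr) in enumerate(rxns):
            if rid.startswith("P"):
                st = dict(st)
                prod = next(k for k, v in st.items() if v > 0)
                st[prod] = 2.0
                rxns[idx] = (rid, st, irr)
                break

    draws = rng.random(len(rxns))
    final = []
    for (rid, st, irr), r in zip(rxns, draws):
        if not rid.startswith("EX") and r < spec.reversible_fraction:
            irr = False
        final.append((rid, st, irr))
    net = make_network(mets, final)
    return net, {"planted_blocked": planted}


def network_family(
    count: int,
    base_seed: int = 0,
    small: bool = False,
) -> list[tuple[MetabolicNetwork, dict]]:
    """A deterministic family of varied test networks.

    Draws generator parameters from a seeded stream: mixed pathway
    counts and lengths, cross-links, planted dead-ends and reversible
    fractions.  ``small=True`` keeps every network within reach of the
    exhaustive minimal-subnetwork oracle (n <= 14); the default family
    stays at n <= 60.
    """
    rng = np.random.default_rng(base_seed)
    out = []
    for k in range(count):
        if small:
            spec = GeneratorSpec(
                n_pathways=2,
                pathway_length=int(rng.integers(1, 3)),
                n_cross_links=int(rng.integers(0, 2)),
                n_planted_deadends=int(rng.integers(0, 2)),
                reversible_fraction=float(rng.uniform(0.0, 0.4)),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            spec = GeneratorSpec(
                n_pathways=int(rng.integers(2, 6)),
                pathway_length=int(rng.integers(2, 7)),
                n_cross_links=int(rng.integers(0, 5)),
                n_planted_deadends=int(rng.integers(0, 5)),
                reversible_fraction=float(rng.uniform(0.0, 0.6)),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        net, truth = generate_network(spec)
        assert net.n <= (14 if small else 60)
        out.append((net, truth))
    return out


def random_core(
    net: MetabolicNetwork,
    fraction: float,
    seed: int,
    blocked: frozenset[int] | None = None,
) -> CoreSet:
    """Seeded uniform core sample from the consistent reactions only.

    ``blocked`` may carry a precomputed blocked set; otherwise the fast
    consistency checker supplies it.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if blocked is None:
        from .consistency import check_consistency
        blocked = check_consistency(net).blocked
    consistent = sorted(frozenset(range(net.n)) - blocked)
    k = int(np.ceil(fraction * len(consistent)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(consistent), size=k, replace=False) if k else []
    return CoreSet(frozenset(consistent[i] for i in chosen))
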