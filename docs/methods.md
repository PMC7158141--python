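# Methods

## Model and assumptions

A metabolic network is the pair (S, I): an m×n stoichiometric matrix
over metabolites × reactions and the index set of irreversible
reactions.  Steady-state flux distributions are the cone
V = { v : S v = 0, v_I ≥ 0 }.  Everything here treats only the sign
structure of the biology: flux bounds, objectives, gene rules and
compartments are out of scope (bounds are carried through I/O and an
optional bounded reconstruction mode, but the analyzed algorithms work
on the homogeneous cone).

Blockedness is a property of V: reaction j is blocked iff v_j = 0 on
all of V.  Because V is closed under addition and positive scaling,
supports of feasible fluxes are closed under union — the fact that
powers every shortcut in this package.

## Consistency checking

*Irreversible reactions.*  One LP maximizes Σ_j z_j over j ∈ I with
z_j ≤ v_j, z_j ≤ 1, v ∈ V.  At any optimum, z_j = 1 (hence v_j ≥ 1)
for every unblockable irreversible j: if some optimum had z_j < 1 with
j unblockable, adding a scaled feasible flux through j would increase
the objective strictly — contradiction.  So a single solve returns a
witness v that simultaneously certifies every retained irreversible
reaction with flux ≥ 1, and everything outside its support is blocked.
A guard pass re-solves over undecided reactions only when the solver's
z- and v-values disagree (a degenerate-vertex signal); it is capped at
log2(n)+1 passes and has never been observed to fire with HiGHS.

*Reversible reactions.*  Given the dense witness, j is unblocked iff
some u ∈ null(S_retained) has u_j ≠ 0, since u + c·v ∈ V for large
c > 0.  This has no sign constraints, so it is linear algebra: one
SVD-based null-space basis (relative rank tolerance 1e-9), and j is
blocked iff its basis row is entirely below the zero tolerance.  The
checker therefore issues at most 2 LPs per network (1 in practice)
against the 2n of the flux-variability oracle, which is kept in the
package as the independent ground truth for testing.

## Graph preprocessing

Boundary reactions have entrywise one-signed columns.  Appending a
fictitious extracellular metabolite whose row is minus the column sums
of W·S (W = diag of a positive mass vector) internalizes them; the row
is computed exactly as the negated column sums, so 1ᵀS′ = 0 holds
bitwise rather than merely to LP tolerance.  Only the *sign* structure
of S′ is needed to build the skeleton digraph (reactant→product arcs
per reaction, a complete bipartite arc set per column), so the
construction also works on networks with no positive mass vector.

With 1ᵀS′ = 0 the stoichiometry factorizes as S′ = ∂F with ∂ the
vertex-arc incidence matrix and F the nonnegative arc-flow table
f_lk = −S′_ik S′_jk / C_k, C_k = ½ Σ_l |S′_lk|.  For any steady flux,
F v is a circulation, so every arc carrying flow lies on a directed
cycle.  Two consequences are kept carefully apart:

* **Per reaction** (used by the filter): all arcs of one active
  reaction share a strongly connected component.  Each arc (i, j) of a
  circulation has comp(i) = comp(j); since a reaction's arc set is
  complete bipartite between its reactants and products, all its
  touched metabolites share one SCC.  This holds unconditionally, so
  `blocked_by_graph` (reactions whose metabolites straddle SCCs) is a
  *sound* pre-filter: it only ever reports truly blocked reactions,
  and the LP checker finds the rest per component.
* **Per support**: the arc set of an entire active support is a union
  of strongly connected pieces, one per weakly connected component.
  It is a *single* strongly connected subgraph only when the support
  is weakly connected — e.g. when all exchanges meet at the shared
  fictitious metabolite.  A sampled counterexample (two disconnected
  cycles active at once) is easy to construct, so the tests assert the
  per-piece property unconditionally and global strong connectivity
  only for weakly connected supports; the acceptance script reports
  both rates.

A reversible reaction is retained iff either split direction is
retained (unblocked in either direction means unblocked).  Splitting
itself is lossless for fluxes (v ↦ (v⁺, v⁻)) but not for blockedness
per copy: the forward/reverse pair forms a futile 2-cycle, so a
blocked reversible reaction can have individually unblocked copies.
The SCC decision is unaffected (both copies touch the same
metabolites), but oracle invariance under splitting is tested in the
sound direction only.

Stoichiometric consistency — existence of molecular masses w with
wᵀS_internal = 0, w > 0 — is decided by one LP on {S_Iᵀ w = 0, w ≥ 1}
(scale is arbitrary, so w ≥ 1 loses nothing; the objective 1ᵀw is
bounded below by m, so unboundedness cannot occur).

## Subnetwork extraction

Phase 1 minimizes the weighted l1 norm of the non-core flux subject to
S v = 0, v ≥ 1 on irreversible core reactions, v ≥ 0 on other
irreversible reactions (elementwise slack w linearizes |·|).  The ≥ 1
scaling keeps every certified flux far above the support tolerance.
N starts as supp(v) ∪ C — the union with C matters because a
reversible *core* reaction can legitimately have zero seed flux; it
must then enter the unverified set B rather than be silently dropped,
or the output could fail to contain the core.  B is exactly the
reversible members of N with |v_j| ≤ tol: v itself already witnesses
everything else.

Phase 2 repeats the randomized witness LP (README).  Design choices
where the printed formulation is silent:

* **Signs in the witness LP**: u_j ≥ 0 is imposed for irreversible
  reactions *outside* N, so newly recruited reactions enter
  forward-feasible; without it the final verification can fail on a
  reaction witnessed only with negative flux.  Irreversible members of
  N stay unconstrained — the u + c·v argument covers them.
* **σ rule boundary**: σ doubles iff |B_after| > |B_before|/2;
  reduction by exactly half counts as sufficient progress (the lenient
  reading, doubling less often).
* **Termination**: the randomized loop has no termination proof, so
  after 3 consecutive iterations with B unchanged, each remaining
  member gets two sign-fixed LPs maximizing ±u_j over the same
  feasible set (w boxed at 1000, a 1e-6 sparsity nudge).  On a
  flux-consistent input this always produces a witness; a member that
  still cannot move is provably inactive and is dropped (hard error if
  it is a core reaction).  The iteration cap defaults to
  20 + 2·log2|B₀|.
* **Certification is authoritative**: a post-run consistency check of
  the induced subnetwork decides the `certified` flag; blocked
  non-core stragglers are removed once and re-verified; a blocked core
  reaction is a hard error.  The reported `lp_count` covers the
  extraction LPs only (seed LP + witness/fallback LPs), with
  certification accounted separately, so the count reflects the
  algorithm itself.
* **Coupling reduction**: merges run to a fixpoint; a merge whose
  combined column would vanish (e.g. a pure 2-cycle) is skipped rather
  than creating an empty column.  With ratio λ < 0 the constituents'
  sign constraints intersect: both irreversible ⇒ the pair is provably
  blocked, dropped and recorded.  A merged reaction is core iff any
  constituent is; its weight is the sum over non-core constituents.
* **SVD initialization** keeps the full numerical-rank null-space
  basis (relative threshold 1e-9).
* **Randomness**: one generator seeded from the options; x is
  resampled over the current B each iteration, making runs
  reproducible bit for bit.

## Tolerances

Support membership uses a single global zero tolerance 1e-6
(configurable); LP feasibility/rank decisions use 1e-9.  Since all
certified fluxes are scaled to ≥ 1, the support tolerance sits six
orders of magnitude below the signal.  The FVA oracle boxes fluxes at
±1000 (blocking in a homogeneous cone is box-independent; spot-checked
at ±10).

## Synthetic data

The generator builds parallel uptake→chain→secretion pathways with
unit stoichiometric coefficients (so the internal part is mass
balanced with w = 1), random one-way cross-links between pathways, and
planted dead-end branches whose terminal metabolite touches exactly
one reaction — blocked by construction, reversibility notwithstanding.
Non-exchange reactions are made reversible by seeded draws (default
fraction 0.3); a flag introduces one non-conserving coefficient for
negative tests.  Default study sizes: families of 100 networks with
n ≤ 60 (mixed 2–5 pathways, lengths 2–6), 30 networks with n ≤ 14 for
the exhaustive-minimality comparison, cores sampled uniformly from the
consistent reactions at fractions 0.1–0.5.

What this does *not* emulate: realistic degree distributions, shared
currency metabolites, compartments, non-unit stoichiometry at scale,
and the cofactor-rich coupling patterns of genome-scale
reconstructions.  Passing tests therefore demonstrate algorithmic
correctness (oracle equivalence, soundness, certification, frugality),
not biological fidelity of extracted subnetworks on real models.

## Known limitations

* The SCC pre-filter is sound but deliberately incomplete; it never
  replaces the LP check.
* Global minimality of extracted subnetworks is not guaranteed
  (NP-hard); at desk scale the extractor matches the exhaustive
  minimum in ≳90% of seeded trials and never undershoots it.
* The reversible blocked test builds a dense null-space basis; fine up
  to a few thousand reactions, but genome-scale models would want a
  sparse rank-revealing factorization behind the same interface.
* One LP backend (HiGHS via scipy) is registered; the solver registry
  accepts others but none are bundled.
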