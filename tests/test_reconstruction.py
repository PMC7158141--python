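import numpy as np
import pytest

from coreprune import (CoreBlockedError, CoreSet, ReconstructionOptions,
                       check_consistency, couple_reduce,
                       extract_subnetwork, extract_subnetwork_iterative,
                       induced_subnetwork, is_consistent_subnetwork,
                       minimal_subnetwork_bruteforce, nullspace_witnesses,
                       sparse_core_flux, witness_step)
from coreprune.lp import LPSession
from coreprune.reconstruction import sigma_update, update_state, \
    ReconstructionState
from coreprune.model import FluxVector
from coreprune import synthetic as syn
from coreprune.synthetic import random_core

from conftest import small_generated


class TestSparseCoreFlux:
    def test_diamond_picks_single_cheapest_route(self, diamond_net):
        session = LPSession()
        core = CoreSet.from_ids(diamond_net, ["R1"])
        v = sparse_core_flux(diamond_net, core, session=session)
        np.testing.assert_allclose(v.values, [1, 1, 0, 1, 0, 1], atol=1e-7)
        assert {diamond_net.reaction_ids[j] for j in v.support()} == \
            {"E1", "R1", "R3", "E2"}
        assert session.count_lps() == 1

    def test_empty_core_gives_zero_flux(self, diamond_net):
        v = sparse_core_flux(diamond_net, CoreSet(frozenset()))
        assert v.support() == set()

    def test_full_core_has_zero_objective(self, chain):
        core = CoreSet(frozenset(range(chain.n)))
        v = sparse_core_flux(chain, core)
        assert np.all(v.values >= 1 - 1e-7)

    def test_blocked_core_reaction_raises(self, chain, dead_end):
        net = syn.disjoint_union(chain, dead_end)
        core = CoreSet.from_ids(net, ["R1'"])  # the dead-end conversion
        with pytest.raises(CoreBlockedError):
            sparse_core_flux(net, core)


class TestWitnessStep:
    def test_aligned_preferences_activate_the_cycle(self, rev_cycle):
        u = witness_step(rev_cycle, {0, 1}, {0, 1},
                         x=np.array([1.0, 1.0]), sigma=1.0)
        np.testing.assert_allclose(u.values, [-1.0, -1.0], atol=1e-7)

    def test_cancelling_preferences_may_stall(self, rev_cycle):
        # objective is identically zero on the feasible line u=(t,t);
        # u = 0 is then among the optima and B need not shrink
        u = witness_step(rev_cycle, {0, 1}, {0, 1},
                         x=np.array([1.0, -1.0]), sigma=1.0)
        t = u.values[0]
        np.testing.assert_allclose(u.values, [t, t], atol=1e-7)

    def test_empty_b_is_a_contract_violation(self, rev_cycle):
        with pytest.raises(ValueError):
            witness_step(rev_cycle, {0, 1}, set(),
                         x=np.array([]), sigma=1.0)


class TestStateUpdates:
    def _state(self):
        return ReconstructionState(
            N={0, 1}, B={0, 1}, witnesses=[],
            v0=FluxVector(np.zeros(3)), sigma=1.0,
        )

    def test_witnessed_reactions_leave_b(self):
        st = self._state()
        update_state(st, FluxVector(np.array([-1.0, -1.0, 0.0])))
        assert st.B == set() and st.N == {0, 1}

    def test_zero_witness_changes_nothing(self):
        st = self._state()
        update_state(st, FluxVector(np.zeros(3)))
        assert st.B == {0, 1} and st.N == {0, 1}

    def test_support_outside_n_recruits(self):
        st = self._state()
        update_state(st, FluxVector(np.array([0.5, 0.0, 0.7])))
        assert st.N == {0, 1, 2} and st.B == {1}

    @pytest.mark.parametrize("before,after,doubles", [
        (10, 6, True),   # 6 > 5: not enough progress
        (10, 5, False),  # exactly half counts as enough
        (10, 0, False),
    ])
    def test_sigma_doubling_rule(self, before, after, doubles):
        assert sigma_update(1.0, before, after) == (2.0 if doubles else 1.0)


class TestNullspaceWitnesses:
    def test_reversible_cycle_has_one_basis_vector(self, rev_cycle):
        ws = nullspace_witnesses(rev_cycle, {0, 1})
        assert len(ws) == 1
        a, b = ws[0].values
        assert a == pytest.approx(b, abs=1e-9)

    def test_full_column_rank_gives_none(self):
        net = syn.make_network(["A", "B"],
                               [("R", {"A": -1, "B": 1}, False)])
        assert nullspace_witnesses(net, {0}) == []

    def test_basis_vectors_are_steady_states(self):
        net, _ = small_generated(4, reversible_fraction=0.5)
        res = check_consistency(net)
        N = set(range(net.n)) - res.blocked
        for u in nullspace_witnesses(net, N):
            assert np.max(np.abs(net.S @ u.values)) <= 1e-9


class TestExtractSubnetwork:
    def test_diamond_core_r1_minimal_and_certified(self, diamond_net):
        core = CoreSet.from_ids(diamond_net, ["R1"])
        res = extract_subnetwork(diamond_net, core,
                                 ReconstructionOptions(rng_seed=0))
        assert res.reaction_ids == ["E1", "E2", "R1", "R3"]
        assert res.certified and res.lp_count == 1
        size, _ = minimal_subnetwork_bruteforce(diamond_net, core)
        assert res.size == size == 4

    def test_empty_core_gives_empty_subnetwork(self, diamond_net):
        res = extract_subnetwork(diamond_net, CoreSet(frozenset()))
        assert res.N == frozenset() and res.certified
        assert res.lp_count == 1

    def test_full_core_returns_whole_consistent_net(self, chain):
        core = CoreSet(frozenset(range(chain.n)))
        res = extract_subnetwork(chain, core)
        assert res.N == frozenset(range(chain.n)) and res.certified

    def test_blocked_core_is_hard_error(self, chain, dead_end):
        net = syn.disjoint_union(chain, dead_end)
        core = CoreSet.from_ids(net, ["E1'"])
        with pytest.raises(CoreBlockedError):
            extract_subnetwork(net, core)

    @pytest.mark.parametrize("seed", range(10))
    def test_validity_on_seeded_pairs(self, seed):
        """Every output is certified, contains the core, and the
        induced subnetwork has no blocked reactions."""
        net, _ = small_generated(seed, reversible_fraction=0.4)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.25, seed + 100, blocked=blocked)
        res = extract_subnetwork(net, core,
                                 ReconstructionOptions(rng_seed=seed))
        assert res.certified
        assert set(core.reaction_indices) <= res.N
        assert is_consistent_subnetwork(net, res.N)

    def test_witness_soundness(self):
        net, _ = small_generated(6, reversible_fraction=0.5)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.3, 1, blocked=blocked)
        res = extract_subnetwork(net, core, ReconstructionOptions(rng_seed=2))
        for u in res.witnesses:
            assert np.max(np.abs(net.S @ u.values)) <= 1e-8

    def test_reduction_and_plain_both_certify(self):
        net, _ = small_generated(8, reversible_fraction=0.4)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.25, 3, blocked=blocked)
        plain = extract_subnetwork(net, core,
                                   ReconstructionOptions(rng_seed=0))
        reduced = extract_subnetwork(
            net, core,
            ReconstructionOptions(rng_seed=0, use_coupling_reduction=True),
        )
        assert plain.certified and reduced.certified
        assert set(core.reaction_indices) <= reduced.N
        assert is_consistent_subnetwork(net, reduced.N)

    def test_svd_init_still_certifies(self):
        net, _ = small_generated(9, reversible_fraction=0.5)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.3, 4, blocked=blocked)
        res = extract_subnetwork(
            net, core, ReconstructionOptions(rng_seed=0, use_svd_init=True)
        )
        assert res.certified

    def test_minimality_on_small_instances(self):
        """|N| never beats the exhaustive minimum and matches it in a
        clear majority of seeded trials."""
        hits = total = 0
        for seed in range(8):
            net, _ = small_generated(
                seed, n_pathways=2, pathway_length=1, n_cross_links=1,
                n_planted_deadends=1, reversible_fraction=0.3,
            )
            assert net.n <= 14
            blocked = check_consistency(net).blocked
            core = random_core(net, 0.25, seed, blocked=blocked)
            res = extract_subnetwork(net, core,
                                     ReconstructionOptions(rng_seed=seed))
            opt, _ = minimal_subnetwork_bruteforce(net, core)
            assert res.size >= opt
            total += 1
            hits += res.size == opt
        assert hits / total >= 0.8


class TestLpAccounting:
    def test_count_is_seed_lp_plus_witness_iterations(self, chain, rev_cycle):
        # core = the reversible cycle: the seed LP leaves it at zero
        # flux, so both reactions enter B and one aligned witness
        # iteration clears them
        net = syn.disjoint_union(chain, rev_cycle)
        core = CoreSet.from_ids(net, ["R1'", "R2"])
        res = extract_subnetwork(net, core, ReconstructionOptions(rng_seed=0))
        assert res.certified
        assert res.iterations >= 1
        assert res.lp_count == 1 + res.iterations  # no fallback LPs here

    def test_monotone_b_and_sigma_only_doubles_on_stagnation(self):
        net, _ = small_generated(13, reversible_fraction=0.6)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.3, 2, blocked=blocked)
        res = extract_subnetwork(net, core, ReconstructionOptions(rng_seed=5))
        hist = res.sigma_history
        assert all(b in (a, 2 * a) for a, b in zip(hist, hist[1:]))


class TestIterativeShrinking:
    def test_already_minimal_converges_in_one_extra_round(self, diamond_net):
        core = CoreSet.from_ids(diamond_net, ["R1"])
        res = extract_subnetwork_iterative(diamond_net, core)
        assert res.size == 4 and res.certified

    def test_size_non_increasing_across_rounds(self):
        net, _ = small_generated(12, reversible_fraction=0.5)
        blocked = check_consistency(net).blocked
        core = random_core(net, 0.2, 7, blocked=blocked)
        one = extract_subnetwork(net, core, ReconstructionOptions(rng_seed=3))
        many = extract_subnetwork_iterative(
            net, core, ReconstructionOptions(rng_seed=3)
        )
        assert many.size <= one.size
        assert many.certified and set(core.reaction_indices) <= many.N
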