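import json

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from coreprune import (CoreSet, FluxVector, MetabolicNetwork,
                       ValidationError, boundary_reactions,
                       induced_subnetwork, load_model, save_model_json,
                       split_reversible)
from coreprune.io import FormatError, load_core_set
from coreprune import synthetic as syn

from conftest import small_generated


class TestValidation:
    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            syn.make_network(
                ["A"], [("R", {"A": 1}, True), ("R", {"A": -1}, True)]
            )

    def test_all_zero_column_rejected(self):
        S = sp.csc_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValidationError, match="all-zero"):
            MetabolicNetwork(["A", "B"], ["R1", "R2"], S, [True, True])

    def test_irreversible_negative_lower_bound_rejected(self):
        S = sp.csc_matrix(np.array([[1.0]]))
        with pytest.raises(ValidationError):
            MetabolicNetwork(["A"], ["R"], S, [True],
                             bounds=np.array([[-5.0, 5.0]]))


class TestBoundary:
    def test_chain_exchanges_are_boundary(self, chain):
        assert {chain.reaction_ids[j]
                for j in boundary_reactions(chain)} == {"E1", "E2"}

    def test_pure_internal_cycle_has_none(self, irr_cycle):
        assert boundary_reactions(irr_cycle) == frozenset()

    def test_one_signed_column_is_boundary(self):
        net = syn.make_network(["A", "B"], [("R", {"A": 2, "B": 3}, True)])
        assert boundary_reactions(net) == {0}


class TestSplitReversible:
    def test_counts_and_columns(self, rev_cycle):
        split, imap = split_reversible(rev_cycle)
        assert split.n == 4 and split.irreversible.all()
        assert imap == [(0, 1), (0, -1), (1, 1), (1, -1)]
        fwd = split.S[:, 0].toarray().ravel()
        rev = split.S[:, 1].toarray().ravel()
        np.testing.assert_array_equal(fwd, -rev)

    def test_irreversible_net_is_identity(self, chain):
        split, imap = split_reversible(chain)
        assert split.n == chain.n
        assert imap == [(j, 1) for j in range(chain.n)]
        assert (split.S != chain.S).nnz == 0

    def test_flux_space_preserved_by_splitting(self):
        # v maps to (v+, v-) in the split net and back, both certified
        net, _ = small_generated(3, reversible_fraction=0.5)
        split, imap = split_reversible(net)
        rng = np.random.default_rng(0)
        from scipy.linalg import null_space
        basis = null_space(net.S.toarray())
        for _ in range(10):
            v = basis @ rng.standard_normal(basis.shape[1])
            v[net.irreversible] = np.abs(v[net.irreversible])
            # project back to the nullspace to restore S v = 0
            v = basis @ (basis.T @ v)
            if not FluxVector(v).is_steady_state(net):
                continue
            parts = np.array([max(v[j], 0) if d > 0 else max(-v[j], 0)
                              for j, d in imap])
            assert FluxVector(parts).is_steady_state(split)

    def test_boundary_maps_through_index_map(self, chain, rev_cycle):
        net = syn.disjoint_union(chain, rev_cycle)
        split, imap = split_reversible(net)
        orig = boundary_reactions(net)
        mapped = {imap[k][0] for k in boundary_reactions(split)}
        assert mapped == orig


class TestInducedSubnetwork:
    def test_full_restriction_is_identity(self, chain):
        sub = induced_subnetwork(chain, range(chain.n))
        assert sub.reaction_ids == chain.reaction_ids
        assert (sub.S != chain.S).nnz == 0

    def test_diamond_restriction_is_linear_pathway(self, diamond_net):
        keep = diamond_net.indices_of(["E1", "R1", "R3", "E2"])
        sub = induced_subnetwork(diamond_net, keep)
        assert sub.n == 4
        # C is now an orphan metabolite row, kept but flagged
        assert diamond_net.metabolite_ids.index("C") in \
            sub.empty_metabolite_rows

    def test_empty_keep_gives_zero_columns(self, chain):
        sub = induced_subnetwork(chain, [])
        assert sub.n == 0 and sub.m == chain.m


class TestJsonRoundTrip:
    def test_fixture_round_trip_exact(self, tmp_path, diamond_net):
        p = tmp_path / "model.json"
        save_model_json(diamond_net, p)
        back = load_model(p)
        assert back.reaction_ids == diamond_net.reaction_ids
        assert back.metabolite_ids == diamond_net.metabolite_ids
        assert (back.S != diamond_net.S).nnz == 0
        np.testing.assert_array_equal(back.irreversible,
                                      diamond_net.irreversible)

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_seeded_round_trip_exact(self, tmp_path, seed):
        net, _ = small_generated(seed, reversible_fraction=0.4)
        p = tmp_path / "m.json"
        save_model_json(net, p)
        back = load_model(p)
        assert (back.S != net.S).nnz == 0
        assert back.reaction_ids == net.reaction_ids
        np.testing.assert_array_equal(back.irreversible, net.irreversible)

    def test_zero_column_file_rejected(self, tmp_path):
        doc = {"metabolites": ["A"],
               "reactions": [{"id": "R1", "irreversible": True},
                             {"id": "R2", "irreversible": True}],
               "stoichiometry": [[0, 0, 1.0]]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            load_model(p)

    def test_malformed_json_names_problem(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(FormatError):
            load_model(p)


class TestSbml:
    def _write_sbml(self, tmp_path, lower):
        cobra = pytest.importorskip("cobra")
        from cobra.io import write_sbml_model
        model = cobra.Model("toy")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")
        r = cobra.Reaction("R1", lower_bound=lower, upper_bound=1000)
        r.add_metabolites({a: -1, b: 1})
        ex_in = cobra.Reaction("EX_in", lower_bound=0, upper_bound=1000)
        ex_in.add_metabolites({a: 1})
        ex_out = cobra.Reaction("EX_out", lower_bound=0, upper_bound=1000)
        ex_out.add_metabolites({b: -1})
        model.add_reactions([r, ex_in, ex_out])
        p = tmp_path / "toy.xml"
        write_sbml_model(model, str(p))
        return p

    def test_negative_lower_bound_means_reversible(self, tmp_path):
        net = load_model(self._write_sbml(tmp_path, -1000))
        assert not net.irreversible[net.reaction_index("R1")]

    def test_nonnegative_lower_bound_means_irreversible(self, tmp_path):
        net = load_model(self._write_sbml(tmp_path, 0))
        assert net.irreversible[net.reaction_index("R1")]


class TestCoreSet:
    def test_load_core_with_comments(self, tmp_path, diamond_net):
        p = tmp_path / "core.txt"
        p.write_text("# the core\nR1\nR3  # inline\n\n")
        core = load_core_set(p, diamond_net)
        assert set(core) == set(diamond_net.indices_of(["R1", "R3"]))

    def test_unknown_id_raises(self, tmp_path, diamond_net):
        p = tmp_path / "core.txt"
        p.write_text("NOPE\n")
        with pytest.raises(KeyError, match="NOPE"):
            load_core_set(p, diamond_net)


@given(values=st.lists(
    st.floats(-10, 10, allow_nan=False), min_size=1, max_size=8),
    tol=st.floats(0, 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_flux_support_definition(values, tol):
    fv = FluxVector(np.array(values), zero_tol=tol)
    assert fv.support() == {
        j for j, v in enumerate(values) if abs(v) > tol
    }
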