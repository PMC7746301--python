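import itertools

import numpy as np
import pytest

from loopstate.model_core import Edge, SignedNetwork
from loopstate.structural_analysis import (
    FeedbackLoop,
    Gauge,
    SignMatrix,
    all_feasible_gauges,
    enumerate_feedback_loops,
    find_monotone_gauge,
    influence_via_gauge,
    input_output_influence,
    input_sign_vector,
    interaction_matrix,
    is_candidate_multistationary,
    is_irreducible,
    monte_carlo_influence_signs,
    random_jacobian_realization,
    structural_influence_matrix,
)

NODES = ("a", "k", "c", "m", "p", "g")

# Known sign tables of the built-in network, row order (a, k, c, m, p, g).
S_EXPECTED = (
    ("-", "0", "0", "-", "0", "0"),
    ("+", "-", "-", "0", "0", "0"),
    ("0", "0", "-", "0", "0", "-"),
    ("0", "0", "0", "-", "+", "-"),
    ("0", "-", "0", "0", "-", "0"),
    ("0", "0", "0", "0", "-", "-"),
)
GAUGED_EXPECTED = (
    ("-", "0", "0", "+", "0", "0"),
    ("+", "-", "+", "0", "0", "0"),
    ("0", "0", "-", "0", "0", "+"),
    ("0", "0", "0", "-", "+", "+"),
    ("0", "+", "0", "0", "-", "0"),
    ("0", "0", "0", "0", "+", "-"),
)
INFLUENCE_EXPECTED = (
    ("+", "+", "-", "-", "-", "+"),
    ("+", "+", "-", "-", "-", "+"),
    ("-", "-", "+", "+", "+", "-"),
    ("-", "-", "+", "+", "+", "-"),
    ("-", "-", "+", "+", "+", "-"),
    ("+", "+", "-", "-", "-", "+"),
)


def _toy_network(edges, nodes=("x", "y"), input_edges=()):
    return SignedNetwork(nodes, tuple(edges), "u", tuple(input_edges))


def _random_sign_matrix(rng, n, p_edge=0.35):
    mat = -np.eye(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p_edge:
                mat[i, j] = rng.choice([-1, 1])
    labels = tuple(f"n{i}" for i in range(n))
    return SignMatrix.from_ints(mat, labels)


class TestInteractionMatrix:
    def test_als_matches_printed_matrix(self, S_als):
        assert S_als.row_labels == NODES
        assert S_als.entries == S_EXPECTED

    def test_pfk3_row(self, S_als):
        assert S_als.entries[NODES.index("k")] == ("+", "-", "-", "0", "0", "0")

    def test_oxphos_row(self, S_als):
        assert S_als.entries[NODES.index("m")] == ("0", "0", "0", "-", "+", "-")

    def test_empty_network_is_pure_decay(self):
        net = _toy_network((), nodes=("x", "y", "z"))
        S = interaction_matrix(net)
        assert S.to_ints().tolist() == (-np.eye(3, dtype=int)).tolist()


class TestInputSignVector:
    def test_als_input_column(self, als_net):
        S_u = input_sign_vector(als_net)
        assert tuple(r[0] for r in S_u.entries) == ("0", "0", "0", "-", "0", "0")

    def test_no_input_edges(self):
        net = _toy_network((Edge("e", "x", "y", 1),))
        assert all(r[0] == "0" for r in input_sign_vector(net).entries)

    def test_two_input_edges(self):
        net = _toy_network(
            (), input_edges=(Edge("i1", "u", "x", 1), Edge("i2", "u", "y", -1))
        )
        S_u = input_sign_vector(net)
        assert tuple(r[0] for r in S_u.entries) == ("+", "-")


class TestLoops:
    def test_als_has_exactly_three_positive_loops(self, S_als):
        loops = enumerate_feedback_loops(S_als)
        assert {L.node_sequence for L in loops} == {
            ("a", "k", "p", "m"),
            ("c", "k", "p", "g"),
            ("a", "k", "p", "g", "m"),
        }
        assert all(L.overall_sign == +1 for L in loops)

    def test_loop_inhibition_counts(self, S_als):
        by_nodes = {L.node_sequence: L for L in enumerate_feedback_loops(S_als)}
        assert by_nodes[("a", "k", "p", "m")].n_negative == 2
        assert by_nodes[("c", "k", "p", "g")].n_negative == 4
        assert by_nodes[("a", "k", "p", "g", "m")].n_negative == 4

    def test_canonical_ordering(self, S_als):
        loops = enumerate_feedback_loops(S_als)
        assert [L.node_sequence for L in loops] == sorted(
            [L.node_sequence for L in loops], key=lambda s: (len(s), s)
        )
        for L in loops:
            assert L.node_sequence[0] == min(L.node_sequence)

    def test_zeroing_shared_edge_removes_all_loops(self, S_als):
        entries = [list(r) for r in S_als.entries]
        entries[NODES.index("p")][NODES.index("k")] = "0"
        S0 = SignMatrix(NODES, NODES, tuple(tuple(r) for r in entries))
        assert enumerate_feedback_loops(S0) == []

    def test_two_node_negative_loop(self):
        net = _toy_network((Edge("e1", "x", "y", 1), Edge("e2", "y", "x", -1)))
        loops = enumerate_feedback_loops(interaction_matrix(net))
        assert len(loops) == 1
        assert loops[0].overall_sign == -1

    def test_loop_invariant_even_negatives(self):
        L = FeedbackLoop(("x", "y"), (-1, -1))
        assert L.is_positive and L.n_negative == 2
        with pytest.raises(ValueError):
            FeedbackLoop(("x", "x"), (1, 1))


class TestCandidateMultistationarity:
    def test_als_is_candidate(self, S_als):
        ok, report = is_candidate_multistationary(enumerate_feedback_loops(S_als))
        assert ok
        assert report["n_loops"] == 3

    def test_no_loops_is_not_candidate(self):
        ok, report = is_candidate_multistationary([])
        assert not ok
        assert report["reason"] == "no loops"

    def test_negative_loop_is_not_candidate(self):
        loops = [FeedbackLoop(("x", "y"), (1, -1))]
        ok, report = is_candidate_multistationary(loops)
        assert not ok
        assert report["negative_loops"] == [("x", "y")]


class TestMonotoneGauge:
    def test_als_gauge_flips_a_k_g(self, S_als):
        g = find_monotone_gauge(S_als)
        assert g is not None
        assert g.flipped_nodes() == ("a", "g", "k")
        assert g.flips["m"] == +1  # canonical form

    def test_gauged_matrix_matches_printed(self, S_als):
        g = find_monotone_gauge(S_als)
        assert g.apply(S_als).entries == GAUGED_EXPECTED

    def test_brute_force_uniqueness_up_to_global_sign(self, S_als):
        gauges = all_feasible_gauges(S_als)
        assert len(gauges) == 2
        flips = {tuple(sorted(g.flips.items())) for g in gauges}
        g = find_monotone_gauge(S_als)
        assert tuple(sorted(g.flips.items())) in flips
        assert tuple(sorted(g.negate().flips.items())) in flips

    def test_all_activation_network_has_identity_gauge(self):
        net = _toy_network(
            (Edge("e1", "x", "y", 1), Edge("e2", "y", "z", 1), Edge("e3", "z", "x", 1)),
            nodes=("x", "y", "z"),
        )
        g = find_monotone_gauge(interaction_matrix(net))
        assert g is not None
        assert g.flipped_nodes() == ()

    def test_negative_loop_has_no_gauge(self):
        net = _toy_network((Edge("e1", "x", "y", 1), Edge("e2", "y", "x", -1)))
        S = interaction_matrix(net)
        assert find_monotone_gauge(S) is None
        assert all_feasible_gauges(S) == []

    def test_balance_equivalence_on_random_digraphs(self, rng):
        # a monotone gauge exists iff the *undirected* signed support is
        # balanced; brute force over all 2^n flip assignments is the oracle.
        # Balance implies all directed cycles positive (the converse fails:
        # mixed-orientation odd structures need no directed cycle at all).
        for _ in range(500):
            n = int(rng.integers(2, 8))
            S = _random_sign_matrix(rng, n)
            loops = enumerate_feedback_loops(S)
            all_positive = all(L.is_positive for L in loops)
            fast = find_monotone_gauge(S)
            brute = all_feasible_gauges(S)
            assert (fast is not None) == bool(brute)
            if fast is not None:
                assert all_positive
                gauged = fast.apply(S)
                assert all(
                    ch != "-"
                    for i, row in enumerate(gauged.entries)
                    for j, ch in enumerate(row)
                    if i != j
                )


class TestStructuralInfluence:
    def test_als_matches_printed_matrix(self, S_als):
        infl, report = structural_influence_matrix(S_als)
        assert infl.entries == INFLUENCE_EXPECTED
        assert not infl.has_unknown
        assert not report["structurally_singular"]

    def test_some_entries_need_the_stability_argument(self, S_als):
        infl, report = structural_influence_matrix(S_als, assume_stability=False)
        assert infl.has_unknown  # term expansion alone cannot sign everything
        _, rep2 = structural_influence_matrix(S_als)
        assert len(rep2["resolved_by_monotonicity"]) > 0

    def test_shortcut_path_agrees(self, S_als):
        assert is_irreducible(S_als)
        assert influence_via_gauge(S_als) == structural_influence_matrix(S_als)[0]

    def test_shortcut_refuses_reducible_support(self):
        net = _toy_network((Edge("e1", "x", "y", 1),))
        S = interaction_matrix(net)
        with pytest.raises(ValueError, match="irreducible"):
            influence_via_gauge(S)

    def test_single_node_influence_is_positive(self):
        S = SignMatrix.from_ints([[-1]], ("x",))
        infl, _ = structural_influence_matrix(S)
        assert infl.entries == (("+",),)

    def test_monte_carlo_oracle_agrees_on_als(self, S_als):
        mc = monte_carlo_influence_signs(S_als, n_draws=300, seed=7)
        assert mc.entries == INFLUENCE_EXPECTED

    def test_unconstrained_sampling_refutes_nothing(self, S_als, rng):
        # definite signs from pure term expansion hold for ALL magnitudes,
        # so even unstable realizations must agree there
        infl, _ = structural_influence_matrix(S_als, assume_stability=False)
        mc = monte_carlo_influence_signs(S_als, n_draws=100, seed=3, require_stable=False)
        for i in range(6):
            for k in range(6):
                if infl.entries[i][k] in ("+", "-", "0"):
                    assert mc.entries[i][k] == infl.entries[i][k]

    def test_symbolic_vs_sampling_on_random_patterns(self, rng):
        n_checked = 0
        for _ in range(100):
            n = int(rng.integers(2, 6))
            S = _random_sign_matrix(rng, n)
            infl, _ = structural_influence_matrix(S, assume_stability=False)
            mc = monte_carlo_influence_signs(
                S, n_draws=40, seed=int(rng.integers(0, 2**31)), require_stable=False
            )
            for i in range(n):
                for k in range(n):
                    sym = infl.entries[i][k]
                    if sym in ("+", "-", "0"):
                        assert mc.entries[i][k] == sym, (S.entries, i, k)
                        n_checked += 1
        assert n_checked > 100

    def test_real_dominant_eigenvalue_across_realizations(self, S_als, rng):
        # monotone sign pattern => Perron-type real dominant eigenvalue
        for _ in range(1000):
            J = random_jacobian_realization(S_als, rng)
            eig = np.linalg.eigvals(J)
            dom = eig[np.argmax(eig.real)]
            assert abs(dom.imag) < 1e-10


class TestInputOutputInfluence:
    def test_als_prediction(self, als_net, S_als):
        io = input_output_influence(S_als, input_sign_vector(als_net))
        assert tuple(r[0] for r in io.entries) == ("+", "+", "-", "-", "-", "+")

    def test_zero_input_vector(self, S_als):
        S_u = SignMatrix.from_ints([[0]] * 6, NODES, ("u",))
        io = input_output_influence(S_als, S_u)
        assert all(r[0] == "0" for r in io.entries)

    def test_consistency_with_oxphos_column(self, als_net, S_als):
        infl, _ = structural_influence_matrix(S_als)
        io = input_output_influence(S_als, input_sign_vector(als_net))
        m = NODES.index("m")
        flip = {"+": "-", "-": "+", "0": "0"}
        assert tuple(r[0] for r in io.entries) == tuple(
            flip[infl.entries[i][m]] for i in range(6)
        )


class TestSignMatrixType:
    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            SignMatrix(("x",), ("x",), (("*",),))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SignMatrix(("x", "y"), ("x",), (("+",),))

    def test_to_ints_rejects_unknown(self):
        S = SignMatrix(("x",), ("x",), (("?",),))
        with pytest.raises(ValueError):
            S.to_ints()

    def test_format_table_contains_labels(self, S_als):
        text = S_als.format_table({"a": "AMPK"}, title="S")
        assert "AMPK" in text and "S" in text
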