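"""Node metrics, modularity, leading-eigenvector communities, rank correlation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix, random_symmetric
from trapnet.netstats import (
    eigenvector_centrality,
    leading_eigenvector_communities,
    membership_agreement,
    modularity,
    round_half_up,
    spearman_rank_correlation,
    strength,
    strengths,
)


def two_cliques(m: int, w: float = 1.0):
    """Two disconnected m-cliques with uniform weight."""
    n = 2 * m
    A = np.zeros((n, n))
    for block in (range(m), range(m, n)):
        for i, j in itertools.combinations(block, 2):
            A[i, j] = A[j, i] = w
    return make_matrix(A)


class TestStrength:
    def test_sums_edge_weights(self):
        net = make_matrix([[0, 0.5, 0.25], [0.5, 0, 0], [0.25, 0, 0]])
        assert strength(net, "A") == pytest.approx(0.75)

    def test_isolated_node_zero(self):
        net = make_matrix([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]])
        assert strength(net, "C") == 0.0

    def test_complete_graph_closed_form(self):
        n, w = 6, 0.3
        A = np.full((n, n), w)
        np.fill_diagonal(A, 0)
        net = make_matrix(A)
        np.testing.assert_allclose(strengths(net), (n - 1) * w)

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            strength(make_matrix(np.zeros((2, 2))), "Z")


def power_iteration(A: np.ndarray, iters: int = 10_000) -> np.ndarray:
    """Independent oracle for the principal eigenvector."""
    v = np.ones(A.shape[0])
    for _ in range(iters):
        nxt = A @ v
        nxt /= np.linalg.norm(nxt)
        if np.allclose(nxt, v, rtol=0.0, atol=1e-14):
            v = nxt
            break
        v = nxt
    return v / v.max()


class TestEigenvectorCentrality:
    def test_complete_graph_all_equal_one(self):
        A = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(eigenvector_centrality(make_matrix(A)), 1.0)

    @pytest.mark.parametrize("n_leaves", [4, 9, 16])
    def test_star_leaf_to_center_ratio(self, n_leaves):
        """Closed form: leaf/center = 1/sqrt(n) for a star with n leaves."""
        n = n_leaves + 1
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 1.0
        cent = eigenvector_centrality(make_matrix(A))
        assert cent[0] == pytest.approx(1.0)
        np.testing.assert_allclose(cent[1:], 1 / np.sqrt(n_leaves), atol=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        A = random_symmetric(rng, 6)
        cent = eigenvector_centrality(make_matrix(A))
        np.testing.assert_allclose(cent, power_iteration(A), atol=1e-8)

    def test_all_zero_matrix_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="all-zero"):
            cent = eigenvector_centrality(make_matrix(np.zeros((3, 3))))
        assert not cent.any()


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(1)
        net = make_matrix(random_symmetric(rng, 5))
        labels = {n: 0 for n in net.roster}
        assert modularity(net, labels) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_split_is_half(self):
        net = two_cliques(4)
        labels = {n: (0 if i < 4 else 1) for i, n in enumerate(net.roster)}
        assert modularity(net, labels) == pytest.approx(0.5)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        net = make_matrix(random_symmetric(rng, 7))
        labels = {n: int(rng.integers(3)) for n in net.roster}
        A, nodes = net.weights, list(net.roster)
        two_w = A.sum()
        s = A.sum(axis=1)
        q = 0.0
        for i in range(7):
            for j in range(7):
                if labels[nodes[i]] == labels[nodes[j]]:
                    q += A[i, j] - s[i] * s[j] / two_w
        q /= two_w
        assert modularity(net, labels) == pytest.approx(q, abs=1e-12)

    def test_zero_weight_network_rejected(self):
        net = make_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="zero total weight"):
            modularity(net, {n: 0 for n in net.roster})


def brute_force_best_modularity(net, max_blocks=4) -> float:
    """Exhaustive modularity maximization over partitions into <= max_blocks.

    The first node's label is fixed at 0 (modularity is label-invariant),
    and Q is recomputed directly from the definition, independent of the
    implementation under test.
    """
    A = net.weights
    n = len(net.roster)
    two_w = A.sum()
    s = A.sum(axis=1)
    B = A - np.outer(s, s) / two_w
    best = -np.inf
    for rest in itertools.product(range(max_blocks), repeat=n - 1):
        lab = np.array((0,) + rest)
        same = lab[:, None] == lab[None, :]
        best = max(best, B[same].sum() / two_w)
    return best


class TestLeadingEigenvector:
    def test_disconnected_triangles_found_as_components(self):
        net = two_cliques(3)
        part = leading_eigenvector_communities(net)
        assert part.n_communities == 2
        labels = [part.labels[n] for n in net.roster]
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_complete_graph_is_one_community(self):
        A = np.ones((6, 6)) - np.eye(6)
        part = leading_eigenvector_communities(make_matrix(A))
        assert part.n_communities == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_attains_brute_force_modularity_on_planted_blocks(self, seed):
        """8-node two-block graphs: recursion reaches the global optimum."""
        rng = np.random.default_rng(seed)
        A = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            same = (i < 4) == (j < 4)
            w = rng.uniform(0.6, 1.0) if same else rng.uniform(0.0, 0.1)
            A[i, j] = A[j, i] = w
        net = make_matrix(A)
        part = leading_eigenvector_communities(net)
        assert part.modularity == pytest.approx(
            brute_force_best_modularity(net), abs=1e-9
        )

    def test_partition_never_worse_than_trivial(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = make_matrix(random_symmetric(rng, 9))
            assert leading_eigenvector_communities(net).modularity >= -1e-12

    def test_labels_contiguous_from_zero(self):
        net = two_cliques(3)
        part = leading_eigenvector_communities(net)
        assert set(part.labels.values()) == set(range(part.n_communities))

    def test_node_relabeling_permutes_everything_consistently(self):
        rng = np.random.default_rng(21)
        A = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            same = (i < 4) == (j < 4)
            A[i, j] = A[j, i] = rng.uniform(0.5, 1.0) if same else rng.uniform(0, 0.1)
        net = make_matrix(A)
        perm = rng.permutation(8)
        roster_p = tuple(net.roster[i] for i in perm)
        net_p = make_matrix(A[np.ix_(perm, perm)], roster=roster_p)
        part, part_p = (
            leading_eigenvector_communities(net),
            leading_eigenvector_communities(net_p),
        )
        assert part.modularity == pytest.approx(part_p.modularity, abs=1e-12)
        pct, _ = membership_agreement(part.labels, part_p.labels,
                                      list(net.roster))
        assert pct == 100
        cent = dict(zip(net.roster, eigenvector_centrality(net)))
        cent_p = dict(zip(net_p.roster, eigenvector_centrality(net_p)))
        for node in net.roster:
            assert cent[node] == pytest.approx(cent_p[node], abs=1e-10)


def test_leading_eigenvector_agrees_with_igraph_reference():
    """Independent cross-check against igraph's implementation."""
    igraph = pytest.importorskip("igraph")
    rng = np.random.default_rng(31)
    A = np.zeros((12, 12))
    for i, j in itertools.combinations(range(12), 2):
        same = (i // 4) == (j // 4)
        A[i, j] = A[j, i] = rng.uniform(0.5, 1.0) if same else rng.uniform(0, 0.05)
    net = make_matrix(A)
    part = leading_eigenvector_communities(net)

    g = igraph.Graph.Weighted_Adjacency(A.tolist(), mode="undirected",
                                        attr="weight")
    ref = g.community_leading_eigenvector(weights="weight")
    assert part.n_communities == len(ref)
    ref_labels = {net.roster[i]: ref.membership[i] for i in range(12)}
    pct, _ = membership_agreement(part.labels, ref_labels, list(net.roster))
    assert pct == 100
    assert part.modularity == pytest.approx(
        g.modularity(ref, weights="weight"), abs=1e-9
    )


class TestMembershipAgreement:
    def test_identical_partitions(self):
        part = {f"n{i}": i % 3 for i in range(12)}
        assert membership_agreement(part, dict(part)) == (100, 0)

    def test_one_individual_moved_of_twenty(self):
        a = {f"n{i}": (0 if i < 10 else 1) for i in range(20)}
        b = dict(a)
        b["n0"] = 1
        pct, n_moved = membership_agreement(a, b)
        assert (pct, n_moved) == (95, 1)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_label_permutation_invariance_vs_exhaustive_matching(self, k):
        """Oracle: best agreement over all label permutations, K <= 5."""
        rng = np.random.default_rng(k)
        a = {f"n{i}": int(rng.integers(k)) for i in range(15)}
        sigma = rng.permutation(k)
        b = {n: int(sigma[c]) for n, c in a.items()}
        assert membership_agreement(a, b)[0] == 100
        # independent oracle on a noisy copy
        noisy = dict(b)
        noisy["n0"] = (noisy["n0"] + 1) % k
        best = 0
        for perm in itertools.permutations(range(k)):
            same = sum(1 for n in a if perm[a[n]] == noisy[n])
            best = max(best, same)
        pct, _ = membership_agreement(a, noisy)
        assert pct == round_half_up(100 * best / 15)

    def test_disjoint_rosters_rejected(self):
        with pytest.raises(ValueError, match="share no individuals"):
            membership_agreement({"a": 0}, {"b": 0})


class TestSpearman:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        assert spearman_rank_correlation(x, x) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rank_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_closed_form_small_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1,0), n = 5
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        assert spearman_rank_correlation(x, y) == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rank_correlation(np.ones(5), np.arange(5.0))

    @given(st.permutations(list(range(8))))
    @settings(derandomize=True, max_examples=30)
    def test_bounded_and_symmetric(self, perm):
        x = np.arange(8.0)
        y = np.array(perm, dtype=float)
        r = spearman_rank_correlation(x, y)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert r == pytest.approx(spearman_rank_correlation(y, x))
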