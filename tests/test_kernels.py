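import numpy as np
import pytest

import omiat
from omiat import kernels as kmod
from omiat import simulate as sim
from omiat.nullmodel import to_composition


def edge_enumeration_oracle(tree, otu_ids, P):
    """Naive per-edge leaf-set sums: (lengths, profiles) without traversal reuse."""
    col = {o: j for j, o in enumerate(otu_ids)}
    lengths, profiles = [], []
    for node in tree.traverse(include_self=False):
        leaves = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        cols = [col[x] for x in leaves if x in col]
        lengths.append(node.length)
        profiles.append(P[:, cols].sum(axis=1) if cols else np.zeros(P.shape[0]))
    return np.array(lengths), np.array(profiles).T


def oracle_unifrac(lengths, prof, kind, alpha=None):
    n = prof.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for e in range(lengths.size):
                pi, pj = prof[i, e], prof[j, e]
                if kind == "unweighted":
                    ai, aj = float(pi > 0), float(pj > 0)
                    num += lengths[e] * abs(ai - aj)
                    den += lengths[e] * (1.0 if (ai or aj) else 0.0)
                elif kind == "weighted":
                    num += lengths[e] * abs(pi - pj)
                    den += lengths[e] * (pi + pj)
                else:
                    s = pi + pj
                    if s > 0:
                        w = lengths[e] * s ** alpha
                        num += w * abs(pi - pj) / s
                        den += w
            D[i, j] = num / den if den > 0 else 0.0
    return D


class TestBrayCurtis:
    def test_hand_values(self):
        P = np.array([[0.75, 0.25], [1 / 3, 2 / 3]])
        D = kmod.bray_curtis(P).values
        np.testing.assert_allclose(D[0, 1], (abs(0.75 - 1 / 3) + abs(0.25 - 2 / 3)) / 2)
        np.testing.assert_allclose(D[0, 1], 0.41667, atol=1e-5)

    def test_identical_and_disjoint(self):
        P = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        D = kmod.bray_curtis(P).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0


class TestBranchProfiles:
    def test_star_tree_leaf_edges(self, tree_factory):
        tree = tree_factory("(A:1,B:1,C:1);")
        P = np.array([[0.2, 0.3, 0.5]])
        bp = kmod.branch_profiles(P, tree, ["A", "B", "C"])
        assert sorted(bp.profiles[0]) == [0.2, 0.3, 0.5]

    def test_root_spanning_edge_is_one(self, tree_factory):
        tree = tree_factory("((A:1,B:1):1,C:1);")
        P = to_composition(np.array([[1.0, 2, 3], [4, 4, 2]]))
        bp = kmod.branch_profiles(P, tree, ["A", "B", "C"])
        assert np.all(bp.profiles <= 1 + 1e-12)
        assert np.all(bp.profiles >= 0)

    def test_matches_bruteforce_on_random_tree(self, rng):
        tree = sim.synth_tree(10, seed=11)
        otu_ids = [t.name for t in tree.tips()]
        P = to_composition(rng.poisson(5, (6, 10)) + 1)
        bp = kmod.branch_profiles(P, tree, otu_ids)
        lengths, prof = edge_enumeration_oracle(tree, otu_ids, P)
        assert np.allclose(sorted(bp.lengths), sorted(lengths))
        # compare edge multisets via sorted (length, profile) fingerprints
        a = sorted(map(tuple, np.round(np.vstack([bp.lengths, bp.profiles]).T, 9).tolist()))
        b = sorted(map(tuple, np.round(np.vstack([lengths, prof]).T, 9).tolist()))
        assert a == b


class TestUniFrac:
    def test_unweighted_two_leaf_hand_value(self, tree_factory):
        tree = tree_factory("(L1:1,L2:2);")
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        bp = kmod.branch_profiles(P, tree, ["L1", "L2"])
        D = kmod.unweighted_unifrac(bp).values
        np.testing.assert_allclose(D[0, 1], 2.0 / 3.0)

    def test_weighted_two_leaf_star(self, tree_factory):
        tree = tree_factory("(L1:1,L2:1);")
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        bp = kmod.branch_profiles(P, tree, ["L1", "L2"])
        np.testing.assert_allclose(kmod.weighted_unifrac(bp).values[0, 1], 1.0)

    def test_disjoint_star_unweighted_is_one(self, tree_factory):
        tree = tree_factory("(A:1,B:2,C:3);")
        P = np.array([[1.0, 0.0, 0.0], [0.0, 0.4, 0.6]])
        bp = kmod.branch_profiles(P, tree, ["A", "B", "C"])
        np.testing.assert_allclose(kmod.unweighted_unifrac(bp).values[0, 1], 1.0)

    @pytest.mark.parametrize("seed,p", [(5, 7), (6, 12), (7, 9)])
    def test_family_matches_bruteforce_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        tree = sim.synth_tree(p, seed=seed)
        otu_ids = [t.name for t in tree.tips()]
        counts = rng.poisson(3, (6, p)) * rng.binomial(1, 0.6, (6, p))
        counts[counts.sum(axis=1) == 0, 0] = 1
        P = to_composition(counts)
        bp = kmod.branch_profiles(P, tree, otu_ids)
        lengths, prof = edge_enumeration_oracle(tree, otu_ids, P)
        np.testing.assert_allclose(kmod.unweighted_unifrac(bp).values,
                                   oracle_unifrac(lengths, prof, "unweighted"),
                                   atol=1e-12)
        np.testing.assert_allclose(kmod.weighted_unifrac(bp).values,
                                   oracle_unifrac(lengths, prof, "weighted"),
                                   atol=1e-12)
        for a in (0.0, 0.5):
            np.testing.assert_allclose(
                kmod.generalized_unifrac(bp, a).values,
                oracle_unifrac(lengths, prof, "generalized", a), atol=1e-12)

    def test_matches_skbio_reference(self, rng):
        from skbio.diversity import beta_diversity

        tree = sim.synth_tree(9, seed=21)
        otu_ids = [t.name for t in tree.tips()]
        counts = rng.poisson(4, (7, 9)) * rng.binomial(1, 0.7, (7, 9))
        counts[counts.sum(axis=1) == 0, 0] = 5
        ids = [f"S{i}" for i in range(7)]
        P = to_composition(counts)
        bp = kmod.branch_profiles(P, tree, otu_ids)
        ref_u = beta_diversity("unweighted_unifrac", counts, ids=ids,
                               taxa=otu_ids, tree=tree)
        ref_w = beta_diversity("weighted_unifrac", counts, ids=ids,
                               taxa=otu_ids, tree=tree, normalized=True)
        np.testing.assert_allclose(kmod.unweighted_unifrac(bp).values,
                                   ref_u.data, atol=1e-10)
        np.testing.assert_allclose(kmod.weighted_unifrac(bp).values,
                                   ref_w.data, atol=1e-10)

    def test_alpha_one_equals_weighted(self, rng):
        tree = sim.synth_tree(8, seed=2)
        P = to_composition(rng.poisson(6, (5, 8)) + 1)
        bp = kmod.branch_profiles(P, tree, [t.name for t in tree.tips()])
        np.testing.assert_allclose(kmod.generalized_unifrac(bp, 1.0).values,
                                   kmod.weighted_unifrac(bp).values, atol=1e-14)

    def test_identical_profiles_zero_for_every_alpha(self, tree_factory):
        tree = tree_factory("((A:1,B:2):1,C:1);")
        P = np.tile([0.2, 0.3, 0.5], (3, 1))
        bp = kmod.branch_profiles(P, tree, ["A", "B", "C"])
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            assert not kmod.generalized_unifrac(bp, a).values.any()

    def test_subtree_invariance(self, rng):
        from omiat.micam import prune_tree

        tree = sim.synth_tree(10, seed=13)
        otu_ids = [t.name for t in tree.tips()]
        members = otu_ids[:5]
        counts = rng.poisson(5, (6, 5)) + 1
        P_sub = to_composition(counts)
        P_full = np.zeros((6, 10))
        P_full[:, [otu_ids.index(m) for m in members]] = P_sub
        bp_full = kmod.branch_profiles(P_full, tree, otu_ids)
        sub = prune_tree(tree, members)
        bp_sub = kmod.branch_profiles(P_sub, sub, members)
        for fn in (kmod.weighted_unifrac, kmod.unweighted_unifrac):
            np.testing.assert_allclose(fn(bp_full).values, fn(bp_sub).values,
                                       atol=1e-12)
        np.testing.assert_allclose(kmod.generalized_unifrac(bp_full, 0.5).values,
                                   kmod.generalized_unifrac(bp_sub, 0.5).values,
                                   atol=1e-12)

    def test_distance_invariants(self, rng):
        tree = sim.synth_tree(8, seed=4)
        counts = rng.poisson(5, (6, 8)) * rng.binomial(1, 0.7, (6, 8))
        counts[counts.sum(axis=1) == 0, 0] = 3
        P = to_composition(counts)
        dists, degenerate = kmod.candidate_distances(
            P, kmod.TreeIndex(tree, [t.name for t in tree.tips()]))
        assert not degenerate
        assert set(dists) == set(kmod.CANDIDATE_MEASURES)
        for d in dists.values():
            V = d.values
            np.testing.assert_allclose(V, V.T)
            np.testing.assert_allclose(np.diag(V), 0.0)
            assert V.min() >= 0 and V.max() <= 1


class TestKernels:
    def test_two_sample_hand_value(self):
        K = kmod.distance_to_kernel(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(K.values, [[1.0, -1.0], [-1.0, 1.0]])

    def test_zero_distance_gives_zero_kernel(self):
        K = kmod.distance_to_kernel(np.zeros((4, 4)))
        np.testing.assert_allclose(K.values, 0.0)

    def test_matches_explicit_centering_matrices(self, rng):
        n = 9
        D = rng.uniform(0.0, 1.0, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        J = np.eye(n) - np.ones((n, n)) / n
        expected = -0.5 * J @ (D ** 2) @ J
        np.testing.assert_allclose(kmod.gower_center(D), expected, atol=1e-12)
        np.testing.assert_allclose(kmod.gower_center(D).sum(axis=1), 0.0,
                                   atol=1e-10)

    def test_psd_repair_keeps_q_nonnegative(self, rng):
        for _ in range(5):
            D = rng.uniform(0, 1, (8, 8))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            K = kmod.distance_to_kernel(D)
            w = np.linalg.eigvalsh(K.values)
            assert w.min() >= -1e-9
            r = rng.normal(size=8)
            fit = omiat.NullFit(np.zeros(8), r, 1.0, "continuous")
            assert kmod.mirkat_statistic(fit, K) >= -1e-9


class TestMirkatStatistic:
    def test_hand_value(self):
        fit = omiat.NullFit(np.zeros(2), np.array([1.0, -1.0]), 1.0, "continuous")
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert kmod.mirkat_statistic(fit, K) == pytest.approx(2.0)

    def test_zero_residuals(self):
        fit = omiat.NullFit(np.zeros(3), np.zeros(3), 1.0, "continuous")
        assert kmod.mirkat_statistic(fit, np.eye(3)) == 0.0

    def test_phi_scales_inverse(self):
        r = np.array([1.0, 2.0, -3.0])
        K = np.eye(3)
        f1 = omiat.NullFit(np.zeros(3), r, 1.0, "continuous")
        f2 = omiat.NullFit(np.zeros(3), r, 2.0, "continuous")
        assert kmod.mirkat_statistic(fit=f1, K=K) == pytest.approx(
            2 * kmod.mirkat_statistic(fit=f2, K=K))
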