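import numpy as np
import pytest
from scipy import stats
from skbio import TreeNode

from phylosym import (
    ValidationError,
    bipartitions,
    normalized_rf,
    phylosymbiosis_test,
    random_topology,
    robinson_foulds,
)
from phylosym.phylosymbiosis import clade_sets, double_factorial_topologies, tree_fingerprint

from conftest import disjoint_caterpillar_orders, make_caterpillar


def dendropy_rf(t1: TreeNode, t2: TreeNode) -> int:
    """Independent Robinson-Foulds oracle via dendropy."""
    import dendropy

    taxa = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=str(t1), schema="newick", taxon_namespace=taxa)
    d2 = dendropy.Tree.get(data=str(t2), schema="newick", taxon_namespace=taxa)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestBipartitions:
    def test_four_leaf_single_split(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        assert bipartitions(t) == {frozenset("CD")}  # canonical side omits A

    def test_star_tree_empty(self):
        t = TreeNode.read(["(A,B,C,D,E);"])
        assert bipartitions(t) == set()

    def test_binary_tree_has_n_minus_3_splits(self, rng):
        for n in (4, 6, 9, 12):
            t = random_topology([f"L{i}" for i in range(n)], seed=rng)
            assert len(bipartitions(t)) == n - 3

    def test_rooting_does_not_change_splits(self, rng):
        t = random_topology([f"L{i}" for i in range(8)], seed=rng)
        splits = bipartitions(t)
        for tip_name in ("L0", "L5"):
            rerooted = t.root_at(t.find(tip_name).parent)
            assert bipartitions(rerooted) == splits

    def test_duplicate_leaves_rejected(self):
        t = TreeNode.read(["((A,A),(B,C));"])
        with pytest.raises(ValidationError):
            bipartitions(t)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        t = random_topology([f"L{i}" for i in range(7)], seed=rng)
        assert robinson_foulds(t, t.copy()) == 0

    def test_disjoint_caterpillars_maximal(self):
        o1, o2 = disjoint_caterpillar_orders(6)
        t1, t2 = make_caterpillar(o1), make_caterpillar(o2)
        assert bipartitions(t1).isdisjoint(bipartitions(t2))
        assert robinson_foulds(t1, t2) == 2 * (6 - 3)

    def test_matches_independent_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            leaves = [f"L{i}" for i in range(n)]
            t1 = random_topology(leaves, seed=rng)
            t2 = random_topology(leaves, seed=rng)
            assert robinson_foulds(t1, t2) == dendropy_rf(t1, t2)

    def test_metric_axioms_on_random_triples(self, rng):
        leaves = [f"L{i}" for i in range(8)]
        for _ in range(50):
            a = random_topology(leaves, seed=rng)
            b = random_topology(leaves, seed=rng)
            c = random_topology(leaves, seed=rng)
            ab, ba = robinson_foulds(a, b), robinson_foulds(b, a)
            assert ab == ba >= 0
            assert robinson_foulds(a, a.copy()) == 0
            assert ab <= robinson_foulds(a, c) + robinson_foulds(c, b)

    def test_leaf_set_mismatch_lists_difference(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,B),(C,E));"])
        with pytest.raises(ValidationError, match="D"):
            robinson_foulds(t1, t2)


class TestNormalizedRF:
    def test_identical_trees_zero(self, rng):
        t = random_topology([f"L{i}" for i in range(9)], seed=rng)
        assert normalized_rf(t, t.copy()) == 0.0

    def test_split_disjoint_trees_one(self):
        o1, o2 = disjoint_caterpillar_orders(8)
        assert normalized_rf(make_caterpillar(o1), make_caterpillar(o2)) == 1.0

    def test_five_leaf_half_by_hand(self):
        # t1 splits {AB, DE}; t2 splits {AB, CE}: one shared of two each
        t1 = TreeNode.read(["((A,B),C,(D,E));"])
        t2 = TreeNode.read(["((A,B),D,(C,E));"])
        assert normalized_rf(t1, t2) == 0.5

    def test_small_trees_rejected(self):
        t = TreeNode.read(["(A,B,C);"])
        with pytest.raises(ValueError):
            normalized_rf(t, t.copy())

    def test_rerooting_invariance(self, rng):
        leaves = [f"L{i}" for i in range(7)]
        t1 = random_topology(leaves, seed=rng)
        t2 = random_topology(leaves, seed=rng)
        base = normalized_rf(t1, t2)
        for name in ("L1", "L4"):
            assert normalized_rf(t1.root_at(t1.find(name).parent), t2) == base

    def test_rooted_mode_uses_clades(self):
        # same unrooted shape, different rootings: unrooted nRF 0, rooted > 0
        t1 = TreeNode.read(["(((A,B),C),(D,E));"])
        t2 = TreeNode.read(["(((D,E),C),(A,B));"])
        assert normalized_rf(t1, t2) == 0.0
        assert clade_sets(t1) != clade_sets(t2)


class TestRandomTopology:
    def test_uniform_over_four_leaf_topologies(self):
        rng = np.random.default_rng(123)
        counts: dict[frozenset, int] = {}
        n_draws = 10_000
        for _ in range(n_draws):
            t = random_topology(list("ABCD"), seed=rng)
            key = frozenset(bipartitions(t))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        freqs = np.array(list(counts.values())) / n_draws
        assert np.all(np.abs(freqs - 1 / 3) <= 0.02)
        chi2 = stats.chisquare(list(counts.values())).pvalue
        assert chi2 > 0.01

    def test_five_leaf_support_is_fifteen(self):
        rng = np.random.default_rng(7)
        seen = set()
        for _ in range(5000):
            t = random_topology(list("ABCDE"), seed=rng)
            seen.add(frozenset(bipartitions(t)))
        assert len(seen) == double_factorial_topologies(5) == 15

    def test_fixed_seed_reproducible(self):
        t1 = random_topology(list("ABCDEFG"), seed=99)
        t2 = random_topology(list("ABCDEFG"), seed=99)
        assert str(t1) == str(t2)


class TestPhylosymbiosisTest:
    def test_identical_trees_p_matches_exact_probability(self):
        leaves = [f"L{i}" for i in range(8)]
        host = random_topology(leaves, seed=5)
        res = phylosymbiosis_test(host, host.copy(), n_random=10_000, seed=6)
        assert res.observed_nrf == 0.0
        exact = 1 / double_factorial_topologies(8)  # 1/10395
        # empirical frequency of an exact topology match: ~Binomial(1e4, 1e-4)
        assert res.p_value <= exact + 4 * np.sqrt(exact / 10_000)

    def test_maximal_incongruence_p_is_one(self):
        o1, o2 = disjoint_caterpillar_orders(6)
        res = phylosymbiosis_test(make_caterpillar(o1), make_caterpillar(o2),
                                  n_random=500, seed=1)
        assert res.observed_nrf == 1.0
        assert res.p_value == 1.0

    def test_p_monotone_in_observed_for_fixed_null(self):
        leaves = [f"L{i}" for i in range(8)]
        host = random_topology(leaves, seed=11)
        results = []
        for micro_seed in range(6):
            micro = random_topology(leaves, seed=micro_seed)
            results.append(phylosymbiosis_test(host, micro, n_random=2000, seed=42))
        results.sort(key=lambda r: r.observed_nrf)
        for a, b in zip(results, results[1:]):
            assert a.p_value <= b.p_value + 1e-12

    def test_add_one_variant_and_counts_consistent(self):
        leaves = [f"L{i}" for i in range(6)]
        host = random_topology(leaves, seed=2)
        micro = random_topology(leaves, seed=3)
        res = phylosymbiosis_test(host, micro, n_random=1000, seed=4)
        assert res.p_value == res.n_better_or_equal / 1000
        assert res.p_value_add_one == (res.n_better_or_equal + 1) / 1001
        assert 0 <= res.p_value <= 1
        assert res.achievable_nrf[0] == 0.0 and res.achievable_nrf[-1] == 1.0

    def test_fingerprints_identify_topology(self):
        leaves = [f"L{i}" for i in range(6)]
        t1 = random_topology(leaves, seed=8)
        t2 = random_topology(leaves, seed=9)
        assert tree_fingerprint(t1) == tree_fingerprint(t1.copy())
        if robinson_foulds(t1, t2) != 0:
            assert tree_fingerprint(t1) != tree_fingerprint(t2)

    def test_seed_determinism(self):
        leaves = [f"L{i}" for i in range(7)]
        host = random_topology(leaves, seed=1)
        micro = random_topology(leaves, seed=2)
        r1 = phylosymbiosis_test(host, micro, n_random=500, seed=77)
        r2 = phylosymbiosis_test(host, micro, n_random=500, seed=77)
        assert r1.to_dict() == r2.to_dict()


def test_internal_split_extractors_agree(rng):
    """The fast null-loop split extraction and the TreeNode-based
    bipartitions must encode the same splits for the same random edges."""
    from phylosym.phylosymbiosis import _edges_to_splits, _edges_to_tree, _random_edges

    for _ in range(50):
        n = int(rng.integers(4, 10))
        leaves = [f"L{i}" for i in range(n)]
        edges = _random_edges(n, rng)
        tree = _edges_to_tree(edges, leaves)
        index = {name: i for i, name in enumerate(sorted(leaves))}
        from_tree = {
            sum(1 << index[x] for x in split) for split in bipartitions(tree)
        }
        assert from_tree == _edges_to_splits(edges, n)
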