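import numpy as np
import pytest
from skbio import TreeNode

from phylosym import GroupingMap, OtuTable, random_topology


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_table():
    """2 samples x 3 OTUs with taxonomy, used across parsing/QC tests."""
    return OtuTable(
        sample_ids=["s1", "s2"],
        otu_ids=["o1", "o2", "o3"],
        counts=np.array([[10.0, 0.0, 5.0], [3.0, 7.0, 2.0]]),
        taxonomy={
            "o1": ("Bacteria", "Firmicutes", "", "", "", "Lactobacillus", ""),
            "o2": ("Bacteria", "Firmicutes", "", "", "", "Streptococcus", ""),
            "o3": ("Bacteria", "Proteobacteria", "", "", "", "", ""),
        },
    )


@pytest.fixture
def three_leaf_tree():
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


def random_table(rng, n_samples=6, n_otus=30, depth=1000) -> OtuTable:
    comps = rng.dirichlet(np.ones(n_otus), size=n_samples)
    counts = np.array([rng.multinomial(depth, c) for c in comps], dtype=float)
    return OtuTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        otu_ids=[f"o{j}" for j in range(n_otus)],
        counts=counts,
    )


def make_caterpillar(leaves) -> TreeNode:
    """Fully pectinate (caterpillar) tree on the given leaf order."""
    leaves = list(leaves)
    newick = f"({leaves[0]}:1,{leaves[1]}:1)"
    for leaf in leaves[2:]:
        newick = f"({newick}:1,{leaf}:1)"
    return TreeNode.read([newick + ";"])


def disjoint_caterpillar_orders(n):
    """Two leaf orderings whose caterpillar trees share no bipartition:
    natural order vs evens-then-odds (every split of the second contains
    leaf 0 together with leaf 2 but not leaf 1, or is a strict interleave)."""
    labels = [f"T{i}" for i in range(n)]
    other = labels[0::2] + labels[1::2]
    return labels, other


def random_binary_tree_with_lengths(leaves, rng, low=0.1, high=2.0) -> TreeNode:
    tree = random_topology(leaves, seed=rng)
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(low, high))
    return tree


def random_rooted_tree(leaves, rng, low=0.1, high=2.0) -> TreeNode:
    """Rooted binary tree (bifurcating root, as UniFrac requires) built by
    random recursive splitting, with uniform branch lengths."""
    leaves = list(leaves)

    def build(subset):
        if len(subset) == 1:
            return TreeNode(name=subset[0], length=float(rng.uniform(low, high)))
        k = int(rng.integers(1, len(subset)))
        picked = rng.permutation(len(subset))
        left = [subset[i] for i in sorted(picked[:k])]
        right = [subset[i] for i in sorted(picked[k:])]
        return TreeNode(length=float(rng.uniform(low, high)),
                        children=[build(left), build(right)])

    tree = build(leaves)
    tree.length = None
    return tree


def grouping_for(table: OtuTable, n_groups: int) -> GroupingMap:
    labels = [f"G{i % n_groups}" for i in range(table.n_samples)]
    return GroupingMap(dict(zip(table.sample_ids, labels)))
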