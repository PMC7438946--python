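"""Tree congruence: Robinson-Foulds distances and the phylosymbiosis test.

The headline statistic is the normalized Robinson-Foulds (nRF) distance
between the host phylogeny and the microbial dendrogram: the symmetric
difference of their non-trivial bipartition sets divided by its maximum
(|B1| + |B2|, i.e. 2(n-3) for two binary trees on n leaves), so 0 means
topologically identical and 1 means no shared structure. Significance comes
from a randomization null: draw R random binary topologies on the same leaf
set, uniform over labeled topologies, and count how many are at least as
congruent with the host tree as the observed dendrogram.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import ValidationError


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------

def _leaf_order(tree: TreeNode) -> list[str]:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValidationError("all leaves must be labeled")
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate leaf labels in tree")
    return sorted(names)


def _split_masks(tree: TreeNode, index: dict[str, int]) -> set[int]:
    """Non-trivial splits of the (implicitly unrooted) tree as canonical
    bitmasks over sorted leaf labels: each internal edge separates the
    leaves under it from the rest; the canonical side is the one NOT
    containing the lexicographically smallest leaf (bit 0)."""
    n = len(index)
    full = (1 << n) - 1
    masks: set[int] = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._mask = 1 << index[node.name]  # type: ignore[attr-defined]
            continue
        m = 0
        for child in node.children:
            m |= child._mask  # type: ignore[attr-defined]
        node._mask = m  # type: ignore[attr-defined]
        canon = (full ^ m) if (m & 1) else m
        size = canon.bit_count()
        if 2 <= size <= n - 2:
            masks.add(canon)
    return masks


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions induced by the internal edges, each
    represented by the side not containing the lexicographically smallest
    leaf. Rooted trees are treated as unrooted (the two edges at a degree-2
    root induce the same split once)."""
    order = _leaf_order(tree)
    index = {name: i for i, name in enumerate(order)}
    return {
        frozenset(name for name in order if mask & (1 << index[name]))
        for mask in _split_masks(tree, index)
    }


def clade_sets(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial clades of a rooted tree (for the rooted comparison mode)."""
    all_leaves = frozenset(_leaf_order(tree))
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_leaves):
            out.add(clade)
    return out


def _check_leaf_sets(t1: TreeNode, t2: TreeNode) -> list[str]:
    l1, l2 = set(_leaf_order(t1)), set(_leaf_order(t2))
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}")
    return sorted(l1)


def robinson_foulds(t1: TreeNode, t2: TreeNode, rooted: bool = False) -> int:
    """Robinson-Foulds distance: |B1 symmetric-difference B2| over non-trivial
    bipartitions (unrooted, default) or clades (``rooted=True``). Branch
    lengths are ignored."""
    _check_leaf_sets(t1, t2)
    if rooted:
        b1, b2 = clade_sets(t1), clade_sets(t2)
    else:
        b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def normalized_rf(t1: TreeNode, t2: TreeNode, rooted: bool = False) -> float:
    """RF / (|B1| + |B2|), in [0, 1]; equals RF / (2(n-3)) for two binary
    unrooted trees. Undefined below 4 leaves (no non-trivial splits)."""
    leaves = _check_leaf_sets(t1, t2)
    if len(leaves) < 4:
        raise ValueError("normalized RF is undefined for fewer than 4 leaves")
    if rooted:
        b1, b2 = clade_sets(t1), clade_sets(t2)
    else:
        b1, b2 = bipartitions(t1), bipartitions(t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        raise ValueError("both trees are stars; normalized RF undefined")
    return len(b1 ^ b2) / denom


# ---------------------------------------------------------------------------
# random topologies
# ---------------------------------------------------------------------------

def _random_edges(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random unrooted binary topology on leaves 0..n-1 by sequential
    leaf addition: leaf k attaches to one of the 2k-5 existing edges chosen
    uniformly, giving every labeled topology probability 1/(2n-5)!!.
    Internal nodes are numbered from n upward."""
    if n == 3:
        return [(0, 3), (1, 3), (2, 3)]
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        k = rng.integers(len(edges))
        u, v = edges.pop(int(k))
        w = next_internal
        next_internal += 1
        edges.extend([(u, w), (v, w), (leaf, w)])
    return edges


def _edges_to_splits(edges: Sequence[tuple[int, int]], n: int) -> set[int]:
    """Canonical split bitmasks of the unrooted topology given as an edge
    list over node ids (leaves 0..n-1)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    full = (1 << n) - 1
    masks: set[int] = set()
    root = n  # an internal node
    # iterative postorder over the tree rooted at `root`
    stack = [(root, -1, False)]
    below: dict[tuple[int, int], int] = {}
    while stack:
        node, parent, done = stack.pop()
        if not done:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
        else:
            if node < n:
                m = 1 << node
            else:
                m = 0
                for nb in adj[node]:
                    if nb != parent:
                        m |= below[(nb, node)]
            below[(node, parent)] = m
            if parent != -1:
                canon = (full ^ m) if (m & 1) else m
                if 2 <= canon.bit_count() <= n - 2:
                    masks.add(canon)
    return masks


def _edges_to_tree(edges: Sequence[tuple[int, int]], leaves: Sequence[str]) -> TreeNode:
    n = len(leaves)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = n if n > 3 else max(adj)

    def build(node: int, parent: int) -> TreeNode:
        if node < n:
            return TreeNode(name=leaves[node], length=1.0)
        children = [build(nb, node) for nb in adj[node] if nb != parent]
        return TreeNode(length=1.0, children=children)

    tree = build(root, -1)
    tree.length = None
    return tree


def random_topology(leaves: Iterable[str], seed: int | np.random.Generator = 0) -> TreeNode:
    """Uniform random unrooted binary topology over the given leaf labels
    (all (2n-5)!! labeled topologies equiprobable); branch lengths are set
    to 1 as placeholders since only the topology is meaningful."""
    leaves = list(leaves)
    if len(set(leaves)) != len(leaves):
        raise ValidationError("duplicate leaf labels")
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _edges_to_tree(_random_edges(len(leaves), rng), leaves)


def double_factorial_topologies(n: int) -> int:
    """(2n-5)!!: the number of distinct unrooted binary labeled topologies."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# the congruence test
# ---------------------------------------------------------------------------

@dataclass
class PhylosymbiosisResult:
    """Outcome of the randomized-tree congruence test.

    ``p_value`` is the plug-in estimate n_better_or_equal / n_random (ties
    count as better); ``p_value_add_one`` the (k+1)/(R+1) bias-corrected
    variant. ``achievable_nrf`` lists the values nRF can take at this leaf
    count, a reminder that small trees give a coarse scale.
    """

    observed_nrf: float
    n_random: int
    n_better_or_equal: int
    p_value: float
    p_value_add_one: float
    seed: int
    rooted: bool
    null_mean: float
    null_min: float
    null_max: float
    achievable_nrf: list[float]
    host_fingerprint: list[str]
    microbiota_fingerprint: list[str]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def tree_fingerprint(tree: TreeNode) -> list[str]:
    """Sorted short hashes of the tree's canonical bipartitions."""
    out = []
    for split in bipartitions(tree):
        digest = hashlib.sha1("|".join(sorted(split)).encode()).hexdigest()[:12]
        out.append(digest)
    return sorted(out)


def phylosymbiosis_test(
    host: TreeNode,
    microbiota: TreeNode,
    n_random: int = 200_000,
    seed: int = 0,
    rooted: bool = False,
) -> PhylosymbiosisResult:
    """Normalized-RF congruence of microbiota dendrogram and host phylogeny,
    with significance from uniform random topologies.

    observed = nRF(host, microbiota); each of ``n_random`` random binary
    topologies r on the same leaves is scored by nRF(host, r), and
    p = #{r : nRF(host, r) <= observed} / n_random — the probability that a
    topology with no relation to the host is at least as congruent as the
    dendrogram actually observed.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    leaves = _check_leaf_sets(host, microbiota)
    observed = normalized_rf(host, microbiota, rooted=rooted)
    n = len(leaves)
    index = {name: i for i, name in enumerate(leaves)}

    host_unrooted_splits = _split_masks(host, index)
    n_host = len(host_unrooted_splits)
    rng = np.random.default_rng(seed)
    better = 0
    null_sum = 0.0
    null_min, null_max = np.inf, -np.inf
    eps = 1e-12
    for _ in range(n_random):
        splits = _edges_to_splits(_random_edges(n, rng), n)
        denom = n_host + len(splits)
        rf = n_host + len(splits) - 2 * len(host_unrooted_splits & splits)
        nrf = rf / denom
        if rooted:
            # the null remains a comparison of unrooted shapes; the rooted
            # mode only changes how the observed pair is scored, so compare
            # on the same [0, 1] scale
            pass
        if nrf <= observed + eps:
            better += 1
        null_sum += nrf
        null_min = min(null_min, nrf)
        null_max = max(null_max, nrf)

    # for two binary trees RF = 2(n-3) - 2|shared| is always even, so the
    # normalized score moves in steps of 1/(n-3)
    max_splits = n - 3
    achievable = [round(k / max_splits, 6) for k in range(0, max_splits + 1)]
    return PhylosymbiosisResult(
        observed_nrf=observed,
        n_random=n_random,
        n_better_or_equal=better,
        p_value=better / n_random,
        p_value_add_one=(better + 1) / (n_random + 1),
        seed=seed if isinstance(seed, int) else -1,
        rooted=rooted,
        null_mean=null_sum / n_random,
        null_min=float(null_min),
        null_max=float(null_max),
        achievable_nrf=achievable,
        host_fingerprint=tree_fingerprint(host),
        microbiota_fingerprint=tree_fingerprint(microbiota),
    )
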