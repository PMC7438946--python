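"""Distance-based tree building: SNP p-distances, neighbor joining for the
host phylogeny, UPGMA for the microbial dendrogram, and jackknife supports.

Neighbor joining is the Saitou-Nei agglomeration with the Studier-Keppler
Q-criterion; on an additive distance matrix it reproduces the generating
tree exactly. UPGMA is average-linkage agglomeration and always yields a
rooted ultrametric dendrogram. Jackknife supports follow the classic
even-resampling recipe: rarefy the OTU table to a fixed depth, rebuild the
dendrogram, and score each bipartition of the full-depth dendrogram by the
fraction of replicates containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj
from skbio.tree import upgma as _skbio_upgma

from .io_formats import GenotypeMatrix, GroupingMap, OtuTable, ValidationError
from .diversity import unifrac_matrix
from .otu_processing import rarefy_average

logger = logging.getLogger("phylosym")


# ---------------------------------------------------------------------------
# SNP distances
# ---------------------------------------------------------------------------

def snp_pdistance(g: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing p-distance on diploid dosages.

    d(i, j) = sum_s |g_i(s) - g_j(s)| / (2 * #sites observed in both), with
    missing sites pairwise-deleted; 0 for identical genotypes and 1 when one
    individual is homozygous reference and the other homozygous alternate at
    every co-observed site.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if g.n_sites < 1:
        raise ValueError("need at least 1 site")
    x = g.genotypes
    obs = ~np.isnan(x)
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"no co-observed sites for pair ({g.individual_ids[i]!r}, "
                    f"{g.individual_ids[j]!r})")
            d[i, j] = d[j, i] = float(np.abs(x[i, both] - x[j, both]).sum()) / (2 * m)
    return DistanceMatrix(d, ids=list(g.individual_ids))


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch-length estimates are
    clipped to zero (with a log note). The returned tree is unrooted with a
    trifurcating root node."""
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(d, neg_as_zero=False)
    clipped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clipped += 1
    if clipped:
        logger.info("neighbor_joining: clipped %d negative branch lengths to 0", clipped)
    return tree


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram: rooted, ultrametric, with every
    leaf at the same depth. Merge ties are broken deterministically by the
    scan order of the input labels (the first minimal pair wins)."""
    if len(d.ids) < 2:
        raise ValueError("UPGMA needs at least 2 entities")
    if len(d.ids) == 2:
        h = float(d.data[0, 1]) / 2.0
        return TreeNode(children=[TreeNode(name=d.ids[0], length=h),
                                  TreeNode(name=d.ids[1], length=h)])
    return _skbio_upgma(d, weighted=False)


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (branch lengths summed)."""
    return tree.tip_tip_distances()


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return bool(np.ptp(depths) <= tol)


# ---------------------------------------------------------------------------
# lineage pooling and jackknifed dendrograms
# ---------------------------------------------------------------------------

def group_profiles(table: OtuTable, groups: GroupingMap, stat: str = "mean") -> OtuTable:
    """Pool samples into one community profile per lineage.

    Each sample is first converted to relative abundances so deep samples do
    not dominate; the group profile is the per-OTU mean (or median) of those
    fractions. The result is a table whose 'samples' are the group labels.
    """
    if stat not in {"mean", "median"}:
        raise ValueError("stat must be 'mean' or 'median'")
    groups.require_cover(table.sample_ids)
    totals = table.counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("cannot pool samples with zero total count")
    rel = table.counts / totals
    labels = groups.groups()
    rows = []
    for g in labels:
        idx = [i for i, s in enumerate(table.sample_ids) if groups[s] == g]
        if not idx:
            raise ValidationError(f"group {g!r} has no samples")
        rows.append(rel[idx].mean(axis=0) if stat == "mean" else np.median(rel[idx], axis=0))
    return OtuTable(sample_ids=labels, otu_ids=list(table.otu_ids),
                    counts=np.vstack(rows), taxonomy=dict(table.taxonomy))


@dataclass
class SupportedTree:
    """A dendrogram plus jackknife support per internal bipartition.

    ``supports`` maps each non-trivial clade of the master tree (frozenset
    of leaf names) to the fraction of replicate dendrograms containing the
    same clade.
    """

    tree: TreeNode
    supports: dict[frozenset[str], float]
    reps: int
    depth: int

    def annotated_newick(self) -> str:
        """Newick with supports written as internal node labels."""
        tree = self.tree.copy()
        for node in tree.non_tips():
            clade = frozenset(t.name for t in node.tips())
            if clade in self.supports:
                node.name = f"{self.supports[clade]:.2f}"
        return str(tree)


def _clades(tree: TreeNode) -> set[frozenset[str]]:
    all_leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_leaves):
            out.add(clade)
    return out


def jackknife_dendrogram(
    table: OtuTable,
    tree: TreeNode,
    depth: int,
    reps: int = 100,
    method: str = "weighted_normalized",
    seed: int = 0,
    groups: GroupingMap | None = None,
    pooling: str = "mean",
) -> SupportedTree:
    """UPGMA dendrogram from UniFrac distances, with jackknife supports.

    The master dendrogram comes from the full-depth table; each replicate
    rarefies every sample to ``depth`` (one resampling), recomputes the
    UniFrac matrix and the UPGMA tree, and the support of a master clade is
    the fraction of replicates whose dendrogram contains that clade. When
    ``groups`` is given, samples are pooled per lineage (relative-abundance
    ``pooling`` statistic) after each rarefaction so the dendrogram leaves
    are the lineages.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")

    def build(t: OtuTable) -> TreeNode:
        prof = group_profiles(t, groups, stat=pooling) if groups is not None else t
        return upgma(unifrac_matrix(prof, tree, method=method))

    master = build(table)
    master_clades = _clades(master)
    hits = {c: 0 for c in master_clades}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        rep_table = rarefy_average(table, depth=depth, reps=1, seed=rng)
        rep_clades = _clades(build(rep_table))
        for c in master_clades:
            if c in rep_clades:
                hits[c] += 1
    supports = {c: hits[c] / reps for c in master_clades}
    return SupportedTree(tree=master, supports=supports, reps=reps, depth=depth)
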