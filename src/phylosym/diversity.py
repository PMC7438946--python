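"""Alpha diversity (ACE, Simpson) and phylogenetic beta diversity (UniFrac).

ACE follows Chao & Lee's abundance-based coverage estimator with the usual
rare/abundant cutoff of 10; Simpson defaults to the complement form
1 - sum(p_i^2). UniFrac distances are computed on a rooted OTU tree with
branch lengths; the weighted variant weights each branch by the absolute
difference in the fraction of reads descending from it, optionally
normalized so distances fall in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .io_formats import GroupingMap, OtuTable, ValidationError

logger = logging.getLogger("phylosym")

UNIFRAC_METHODS = ("weighted", "weighted_normalized", "unweighted")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def ace_index(counts: Sequence[float], rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness (Chao & Lee).

    With S_abund the number of OTUs with count > ``rare_cutoff``, S_rare the
    OTUs with 1 <= count <= cutoff, F_i the number of OTUs observed exactly i
    times, N_rare the reads in rare OTUs and sample coverage
    C = 1 - F_1/N_rare:

        gamma^2 = max(0, S_rare/C * sum_i i(i-1)F_i / (N_rare(N_rare-1)) - 1)
        ACE     = S_abund + S_rare/C + F_1/C * gamma^2

    When every rare OTU is a singleton the coverage is zero and the estimator
    is undefined; the function falls back to Chao1 (bias-corrected) with a
    logged warning, the convention of the classic mothur/QIIME tools.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("ACE needs at least one positive count")
    s_abund = int(np.sum(c > rare_cutoff))
    rare = c[c <= rare_cutoff]
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    f = np.array([np.sum(rare == i) for i in range(1, rare_cutoff + 1)], dtype=float)
    f1 = f[0]
    n_rare = rare.sum()
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        logger.warning("ace_index: all rare OTUs are singletons; falling back to Chao1")
        return chao1_index(counts)
    i = np.arange(1, rare_cutoff + 1)
    gamma_sq = max(0.0, (s_rare / coverage) * np.sum(i * (i - 1) * f) /
                   (n_rare * (n_rare - 1)) - 1.0) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / coverage + (f1 / coverage) * gamma_sq)


def chao1_index(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    f1 = np.sum(c == 1)
    f2 = np.sum(c == 2)
    return float(c.size + f1 * (f1 - 1) / (2 * (f2 + 1)))


def simpson_index(counts: Sequence[float], variant: str = "complement") -> float:
    """Simpson diversity from squared relative abundances.

    ``complement`` (default) returns 1 - sum(p^2); ``dominance`` the raw
    sum(p^2); ``inverse`` 1/sum(p^2).
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Simpson index needs at least one positive count")
    d = float(np.sum((c / total) ** 2))
    if variant == "complement":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def observed_otus(counts: Sequence[float]) -> int:
    return int(np.sum(np.asarray(counts) > 0))


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _check_leaves(tree: TreeNode, otu_ids: Sequence[str], counts: np.ndarray) -> None:
    leaves = {t.name for t in tree.tips()}
    present = np.asarray(counts).sum(axis=0) > 0 if np.ndim(counts) == 2 else np.asarray(counts) > 0
    missing = [o for o, p in zip(otu_ids, present) if p and o not in leaves]
    if missing:
        raise ValidationError(f"OTUs with positive counts absent from the tree: {missing}")


def weighted_unifrac(
    tree: TreeNode,
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    otu_ids: Sequence[str],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two count vectors over ``otu_ids``.

    raw = sum_branches b * |p_A - p_B| with p_X the fraction of sample X's
    reads descending from the branch; the normalized variant divides by
    sum_branches b * (p_A + p_B), bounding the result by 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    _check_leaves(tree, otu_ids, np.vstack([a, b]))
    counts, ids = _as_integer_counts(np.vstack([a, b]), list(otu_ids))
    from skbio.diversity.beta import weighted_unifrac as _skbio_wu

    return float(_skbio_wu(counts[0], counts[1], taxa=ids, tree=tree,
                           normalized=normalized))


def unifrac_matrix(
    table: OtuTable,
    tree: TreeNode,
    method: str = "weighted_normalized",
) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix over the table's samples."""
    if method not in UNIFRAC_METHODS:
        raise ValueError(f"unknown UniFrac method {method!r}; choose from {UNIFRAC_METHODS}")
    _check_leaves(tree, table.otu_ids, table.counts)
    counts, ids = _as_integer_counts(table.counts, table.otu_ids)
    metric = {"weighted": "weighted_unifrac",
              "weighted_normalized": "weighted_unifrac",
              "unweighted": "unweighted_unifrac"}[method]
    return beta_diversity(metric, counts, ids=table.sample_ids, taxa=ids,
                          tree=tree, normalized=(method == "weighted_normalized"))


_PROFILE_SCALE = 10 ** 6


def _as_integer_counts(counts: np.ndarray, otu_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """UniFrac is a function of relative abundances; fractional profiles
    (pooled lineage means) are rescaled to integer pseudo-counts per million
    so the integer-count computation applies."""
    counts = np.asarray(counts, dtype=float)
    if np.allclose(counts, np.rint(counts)):
        return np.rint(counts).astype(np.int64), otu_ids
    totals = counts.sum(axis=1, keepdims=True)
    scaled = np.rint(counts / totals * _PROFILE_SCALE).astype(np.int64)
    return scaled, otu_ids


# ---------------------------------------------------------------------------
# alpha diversity report
# ---------------------------------------------------------------------------

@dataclass
class AlphaDiversityReport:
    """Per-sample richness/diversity with per-group summaries and pairwise
    group comparisons (Tukey-Kramer on the per-sample values)."""

    per_sample: pd.DataFrame       # index sample, columns observed_otus/ACE/Simpson/group
    per_group: pd.DataFrame        # index (group, metric) -> mean, se, n
    pairwise: pd.DataFrame         # metric, group1, group2, p
    source: str                    # which table the values were computed on


def alpha_diversity_report(
    table: OtuTable,
    groups: GroupingMap,
    rare_cutoff: int = 10,
    source: str = "unspecified",
) -> AlphaDiversityReport:
    from .differential_abundance import tukey_kramer

    groups.require_cover(table.sample_ids)
    rows = []
    for i, s in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append({"sample": s, "group": groups[s],
                     "observed_otus": observed_otus(c),
                     "ACE": ace_index(c, rare_cutoff=rare_cutoff),
                     "Simpson": simpson_index(c)})
    per_sample = pd.DataFrame(rows).set_index("sample")

    summaries = []
    pairwise_rows = []
    grouping = {s: groups[s] for s in table.sample_ids}
    for metric in ("observed_otus", "ACE", "Simpson"):
        for g, sub in per_sample.groupby("group", sort=False):
            vals = sub[metric].to_numpy(dtype=float)
            summaries.append({"group": g, "metric": metric,
                              "mean": vals.mean(),
                              "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                              "n": len(vals)})
        values = dict(zip(per_sample.index, per_sample[metric]))
        try:
            for (g1, g2), p in tukey_kramer(values, GroupingMap(grouping)):
                pairwise_rows.append({"metric": metric, "group1": g1, "group2": g2, "p": p})
        except ValueError:
            logger.warning("alpha_diversity_report: pairwise comparison skipped for %s", metric)
    per_group = pd.DataFrame(summaries).set_index(["group", "metric"])
    pairwise = pd.DataFrame(pairwise_rows, columns=["metric", "group1", "group2", "p"])
    return AlphaDiversityReport(per_sample=per_sample, per_group=per_group,
                                pairwise=pairwise, source=source)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Labeled square TSV."""
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
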