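"""OTU-table quality control: abundance filtering, rarefaction averaging,
log2 z-normalization, taxonomic aggregation, and shared-OTU (Venn) summaries.

The chain mirrors the common 16S workflow: discard OTUs carrying less than a
fixed fraction of all reads, average many even resamplings at 90% of the
minimum sample depth to even out sequencing effort, then log2-transform and
z-score each sample so its abundance profile has mean 0 and unit standard
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .io_formats import (
    RANKS,
    EmptyInputError,
    GroupingMap,
    NormalizedTable,
    OtuTable,
    ValidationError,
)

logger = logging.getLogger("phylosym")


def filter_low_abundance(table: OtuTable, min_total_fraction: float = 1e-5) -> OtuTable:
    """Drop OTUs whose total count across all samples is below a fraction of
    the grand total.

    An OTU is retained iff its column sum is >= ``min_total_fraction`` times
    the grand total (i.e. strictly-less-abundant OTUs are discarded). The
    default 1e-5 is the conventional 0.001% cutoff.
    """
    if not 0 < min_total_fraction < 1:
        raise ValueError("min_total_fraction must be in (0, 1)")
    if table.n_otus == 0 or table.n_samples == 0 or table.grand_total() == 0:
        raise EmptyInputError("cannot filter an empty OTU table")
    threshold = min_total_fraction * table.grand_total()
    totals = table.counts.sum(axis=0)
    keep = [otu for otu, t in zip(table.otu_ids, totals) if t >= threshold]
    logger.info("filter_low_abundance: %d -> %d OTUs (threshold %.4g reads)",
                table.n_otus, len(keep), threshold)
    return table.subset_otus(keep)


def rarefy_average(
    table: OtuTable,
    depth: int | str = "auto",
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    rounding: str = "half_away",
) -> OtuTable:
    """Averaged, rounded rarefied table: mean of ``reps`` even resamplings.

    Each replicate draws ``depth`` reads per sample without replacement
    (multivariate hypergeometric, the classic rarefaction model).
    ``depth="auto"`` uses floor(0.9 x minimum sample total). The replicate
    mean is rounded to integers, by default half-away-from-zero
    (``rounding="half_even"`` selects banker's rounding).
    """
    if table.n_samples == 0 or table.n_otus == 0:
        raise EmptyInputError("cannot rarefy an empty OTU table")
    counts = np.asarray(np.rint(table.counts), dtype=np.int64)
    if not np.allclose(counts, table.counts):
        raise ValidationError("rarefaction requires integer counts")
    totals = counts.sum(axis=1)
    if depth == "auto":
        depth = int(np.floor(0.9 * totals.min()))
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    undersized = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if undersized:
        raise ValueError(f"samples shallower than depth {depth}: {undersized}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = np.zeros_like(counts, dtype=float)
    for _ in range(reps):
        for i in range(table.n_samples):
            acc[i] += rng.multivariate_hypergeometric(counts[i], depth)
    mean = acc / reps
    if rounding == "half_away":
        out = np.floor(mean + 0.5)
    elif rounding == "half_even":
        out = np.rint(mean)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    result = OtuTable(sample_ids=list(table.sample_ids), otu_ids=list(table.otu_ids),
                      counts=out, taxonomy=dict(table.taxonomy))
    result.rarefaction_depth = depth  # type: ignore[attr-defined]
    return result


def normalize_log2_z(table: OtuTable, pseudocount: float = 1.0) -> NormalizedTable:
    """Per-sample log2 z-scores: v = log2(count + pseudocount), then
    (v - mean(v)) / sd(v) within each sample (sample standard deviation,
    ddof=1), so every sample row ends with mean 0 and sd 1."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if table.n_otus < 2:
        raise EmptyInputError("normalization needs at least 2 OTUs")
    v = np.log2(table.counts + pseudocount)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    flat = [s for s, x in zip(table.sample_ids, sd.ravel()) if x == 0]
    if flat:
        raise ValidationError(f"zero variance after log2 transform in samples: {flat}")
    return NormalizedTable(sample_ids=list(table.sample_ids),
                           otu_ids=list(table.otu_ids),
                           counts=(v - mean) / sd,
                           taxonomy=dict(table.taxonomy))


def aggregate_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing a taxonomy label at ``rank``.

    OTUs whose lineage is empty at that rank pool into ``Unassigned``. The
    grand total is conserved. Output rows are labeled by the rank label and
    carry a truncated lineage (ranks below ``rank`` blank).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose one of {RANKS}")
    if not table.taxonomy:
        raise ValidationError("table has no taxonomy to aggregate")
    pos = RANKS.index(rank)
    labels: list[str] = []
    label_index: dict[str, int] = {}
    cols: list[np.ndarray] = []
    lineages: dict[str, tuple[str, ...]] = {}
    for j, otu in enumerate(table.otu_ids):
        lineage = table.taxonomy.get(otu, ("",) * len(RANKS))
        label = lineage[pos] or "Unassigned"
        if label not in label_index:
            label_index[label] = len(labels)
            labels.append(label)
            cols.append(table.counts[:, j].astype(float).copy())
            trunc = tuple(lineage[:pos + 1]) + ("",) * (len(RANKS) - pos - 1)
            lineages[label] = trunc if label != "Unassigned" else ("",) * len(RANKS)
        else:
            cols[label_index[label]] += table.counts[:, j]
    return OtuTable(sample_ids=list(table.sample_ids), otu_ids=labels,
                    counts=np.column_stack(cols) if cols else np.zeros((table.n_samples, 0)),
                    taxonomy=lineages)


@dataclass
class VennSummary:
    """Exact k-set Venn partition of OTU presence across groups.

    ``region_counts`` maps each non-empty subset of groups (as a frozenset)
    to the number of OTUs present in exactly those groups; the counts sum to
    the number of distinct OTUs present anywhere. ``shared_fraction`` is the
    core (present in every group) over the union.
    """

    groups: list[str]
    presence: dict[str, frozenset[str]]
    region_counts: dict[frozenset[str], int]
    shared_fraction: float

    @property
    def core_count(self) -> int:
        return self.region_counts.get(frozenset(self.groups), 0)

    @property
    def union_count(self) -> int:
        return sum(self.region_counts.values())


def shared_otu_summary(table: OtuTable, groups: GroupingMap) -> VennSummary:
    """Venn summary of OTU presence per lineage: an OTU is 'present' in a
    group when its total count over that group's samples is > 0."""
    groups.require_cover(table.sample_ids)
    labels = groups.groups()
    if len(labels) < 2:
        raise ValidationError("Venn summary needs at least 2 groups")
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    presence: dict[str, frozenset[str]] = {}
    for g in labels:
        rows = [sample_index[s] for s in groups.members(g) if s in sample_index]
        if not rows:
            raise ValidationError(f"group {g!r} has no samples in the table")
        totals = table.counts[rows].sum(axis=0)
        presence[g] = frozenset(o for o, t in zip(table.otu_ids, totals) if t > 0)

    region_counts: dict[frozenset[str], int] = {}
    union = frozenset().union(*presence.values())
    for otu in union:
        members = frozenset(g for g in labels if otu in presence[g])
        region_counts[members] = region_counts.get(members, 0) + 1
    core = frozenset(labels)
    shared = region_counts.get(core, 0) / len(union) if union else 0.0
    return VennSummary(groups=labels, presence=presence,
                       region_counts=region_counts, shared_fraction=shared)


def venn_region_table(summary: VennSummary) -> list[tuple[str, int]]:
    """Flatten the Venn partition into (region label, count) rows, ordered by
    subset size then lexicographically; handy for reports."""
    rows = []
    for r in range(1, len(summary.groups) + 1):
        for combo in combinations(sorted(summary.groups), r):
            key = frozenset(combo)
            if key in summary.region_counts:
                rows.append(("&".join(combo), summary.region_counts[key]))
    return rows
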