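"""Multi-group differential relative-abundance testing.

Per taxon: one-way fixed-effects ANOVA across lineages, Tukey-Kramer
studentized-range pairwise comparisons (valid for unequal group sizes), and
Benjamini-Hochberg control of the false discovery rate across taxa. Group
means are reported with standard errors (sd/sqrt(n)) on the tested scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GroupingMap, NormalizedTable, OtuTable
from .otu_processing import aggregate_taxonomy, normalize_log2_z

logger = logging.getLogger("phylosym")


def _split_by_group(values: Mapping[str, float], groups: GroupingMap) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {}
    for sample, v in values.items():
        out.setdefault(groups[sample], []).append(float(v))
    split = {g: np.asarray(v) for g, v in out.items()}
    if len(split) < 2:
        raise ValueError("need at least 2 groups")
    small = [g for g, v in split.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    return split


def anova_oneway(values: Mapping[str, float], groups: GroupingMap) -> tuple[float, float]:
    """Classical one-way ANOVA F test across groups.

    Degenerate inputs follow explicit conventions: if every value is equal
    the comparison is vacuous (F=0, p=1, warning); if within-group variance
    is zero everywhere but means differ, the separation is infinitely strong
    (F=inf, p=0, warning).
    """
    split = _split_by_group(values, groups)
    arrays = list(split.values())
    pooled = np.concatenate(arrays)
    within_var = sum(float(np.var(a)) for a in arrays)
    if within_var == 0.0:
        if np.ptp(pooled) == 0.0:
            warnings.warn("anova_oneway: all values identical; degenerate comparison")
            return 0.0, 1.0
        warnings.warn("anova_oneway: zero within-group variance with unequal means")
        return np.inf, 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_kramer(values: Mapping[str, float], groups: GroupingMap) -> list[tuple[tuple[str, str], float]]:
    """Studentized-range pairwise p-values for every unordered group pair.

    Uses the Tukey HSD statistic with the Kramer adjustment for unequal
    group sizes. Output order follows first appearance of the groups.
    """
    split = _split_by_group(values, groups)
    labels = list(split.keys())
    res = stats.tukey_hsd(*[split[g] for g in labels])
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(((labels[i], labels[j]), float(res.pvalue[i, j])))
    return out


@lru_cache(maxsize=32)
def _studentized_sf_table(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Survival function of the studentized range on a fixed grid, used to
    interpolate many Tukey-Kramer p-values at once (scipy evaluates the
    distribution by quadrature, ~10 ms per point, far too slow per taxon).
    Interpolation on log-sf is accurate to ~1e-6 over the grid range."""
    grid = np.concatenate([np.linspace(1e-9, 8.0, 201), np.linspace(8.06, 30.0, 120)])
    sf = stats.studentized_range.sf(grid, k=k, df=df)
    sf = np.clip(sf, 1e-300, 1.0)
    return grid, np.log(sf)


def _tukey_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    grid, log_sf = _studentized_sf_table(k, df)
    out = np.exp(np.interp(q, grid, log_sf))
    out[q <= grid[0]] = 1.0
    return np.minimum(out, 1.0)


def _batched_tests(tested: np.ndarray, group_rows: list[list[int]]):
    """Vectorized per-taxon one-way ANOVA and Tukey-Kramer pairwise tests.

    ``tested`` is samples x taxa; ``group_rows`` lists each group's row
    indices. Returns (F, p_anova, pair_index_list, pairwise_p) with the
    same degenerate-input conventions as :func:`anova_oneway`.
    """
    k = len(group_rows)
    sizes = np.array([len(r) for r in group_rows])
    n_total = int(sizes.sum())
    df_within = n_total - k
    means = np.stack([tested[r].mean(axis=0) for r in group_rows])          # k x T
    ss_within = np.stack([((tested[r] - means[g]) ** 2).sum(axis=0)
                          for g, r in enumerate(group_rows)]).sum(axis=0)   # T
    grand = tested[np.concatenate(group_rows)].mean(axis=0)
    ss_between = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
    msw = ss_within / df_within
    msb = ss_between / (k - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
        p = stats.f.sf(f, k - 1, df_within)
    degenerate = msw == 0
    flat = degenerate & (msb == 0)
    f = np.where(degenerate, np.inf, f)
    p = np.where(degenerate, 0.0, p)
    f = np.where(flat, 0.0, f)
    p = np.where(flat, 1.0, p)

    pair_idx = [(a, b) for a in range(k) for b in range(a + 1, k)]
    pair_p = np.empty((len(pair_idx), tested.shape[1]))
    for row, (a, b) in enumerate(pair_idx):
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            q = np.abs(means[a] - means[b]) / se
        pp = _tukey_sf(np.where(np.isfinite(q), q, 0.0), k, df_within)
        diff = np.abs(means[a] - means[b]) > 0
        pp = np.where(np.isfinite(q), pp, np.where(diff, 0.0, 1.0))
        pair_p[row] = pp
    return f, p, pair_idx, pair_p


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values: q_(i) = min_{j>=i} p_(j) * m / j, clipped
    at 1; invariant to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffAbundanceResult:
    """Per-taxon ANOVA + pairwise comparison report at one taxonomic rank.

    ``table`` has one row per taxon (ANOVA F/p, BH q, per-group mean/SE on
    both the tested scale and as relative-abundance percentages);
    ``pairwise`` one row per taxon x group pair with the Tukey-Kramer p.
    ``significant`` restricts to taxa with any pairwise p < alpha.
    """

    rank: str
    scale: str
    alpha: float
    table: pd.DataFrame
    pairwise: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        if self.pairwise.empty:
            return self.table.iloc[0:0]
        hits = self.pairwise[self.pairwise["p"] < self.alpha]["taxon"].unique()
        return self.table[self.table.index.isin(hits)]

    def report_rows(self) -> pd.DataFrame:
        """Significant pairwise comparisons formatted as
        taxon / group1 (mean +/- SE) / group2 (mean +/- SE) / p / q rows."""
        rows = []
        for _, r in self.pairwise[self.pairwise["p"] < self.alpha].iterrows():
            t = r["taxon"]
            rows.append({
                "taxon": t,
                "group1": f"{r['group1']} ({self.table.loc[t, 'mean_' + r['group1']]:.3g} "
                          f"± {self.table.loc[t, 'se_' + r['group1']]:.2g})",
                "group2": f"{r['group2']} ({self.table.loc[t, 'mean_' + r['group2']]:.3g} "
                          f"± {self.table.loc[t, 'se_' + r['group2']]:.2g})",
                "p": r["p"],
                "q_anova_bh": self.table.loc[t, "q"],
            })
        return pd.DataFrame(rows, columns=["taxon", "group1", "group2", "p", "q_anova_bh"])


def differential_abundance(
    table: OtuTable,
    groups: GroupingMap,
    rank: str | None = None,
    alpha: float = 0.05,
    scale: str = "normalized",
    pseudocount: float = 1.0,
) -> DiffAbundanceResult:
    """Test every taxon at ``rank`` for between-lineage abundance differences.

    ``scale="normalized"`` (default) tests per-sample log2 z-scores of the
    aggregated counts; ``scale="relative"`` tests relative-abundance
    percentages directly. BH adjustment is applied across the taxa of this
    rank only. Relative-abundance percentages are always reported alongside
    whichever scale was tested.
    """
    if scale not in {"normalized", "relative"}:
        raise ValueError("scale must be 'normalized' or 'relative'")
    groups.require_cover(table.sample_ids)
    agg = aggregate_taxonomy(table, rank) if rank is not None else table
    if agg.n_otus == 0:
        empty = pd.DataFrame()
        return DiffAbundanceResult(rank=rank or "otu", scale=scale, alpha=alpha,
                                   table=empty,
                                   pairwise=pd.DataFrame(columns=["taxon", "group1", "group2", "p"]))

    totals = agg.counts.sum(axis=1, keepdims=True)
    rel_pct = np.divide(agg.counts, totals, out=np.zeros_like(agg.counts),
                        where=totals > 0) * 100.0
    if scale == "normalized" and not isinstance(agg, NormalizedTable):
        tested = normalize_log2_z(agg, pseudocount=pseudocount).counts
    elif scale == "normalized":
        tested = agg.counts
    else:
        tested = rel_pct

    labels = groups.groups()
    group_rows = [[i for i, s in enumerate(agg.sample_ids) if groups[s] == g]
                  for g in labels]
    small = [g for g, r in zip(labels, group_rows) if len(r) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    f_arr, p_arr, pair_idx, pair_p = _batched_tests(tested, group_rows)

    rows = []
    pairwise_rows = []
    for j, taxon in enumerate(agg.otu_ids):
        row: dict[str, float | str] = {"taxon": taxon, "F": float(f_arr[j]),
                                       "p": float(p_arr[j])}
        for g, idx in zip(labels, group_rows):
            vals = tested[idx, j]
            rel = rel_pct[idx, j]
            n = len(idx)
            row[f"mean_{g}"] = float(vals.mean())
            row[f"se_{g}"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            row[f"rel_mean_{g}"] = float(rel.mean())
            row[f"rel_se_{g}"] = float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(row)
        for r, (a, b) in enumerate(pair_idx):
            pairwise_rows.append({"taxon": taxon, "group1": labels[a],
                                  "group2": labels[b], "p": float(pair_p[r, j])})

    result = pd.DataFrame(rows).set_index("taxon")
    result["q"] = benjamini_hochberg(np.nan_to_num(p_arr, nan=1.0))
    pairwise = pd.DataFrame(pairwise_rows, columns=["taxon", "group1", "group2", "p"])
    logger.info("differential_abundance: %d taxa tested at rank %s (%s scale)",
                len(result), rank or "otu", scale)
    return DiffAbundanceResult(rank=rank or "otu", scale=scale, alpha=alpha,
                               table=result, pairwise=pairwise)
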