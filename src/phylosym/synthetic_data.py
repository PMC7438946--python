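"""Synthetic study generator: host tree, SNP genotypes, OTU reference tree,
and lineage-structured gut communities.

The generator emulates the statistical shape of a multi-lineage 16S study:
five host lineages (one with 9 samples, the others 10, n = 49 in the
default layout), a few thousand OTUs, uneven log-normal sequencing depths,
and a tunable phylosymbiosis signal. Lineage community profiles evolve
along the host tree as Brownian motion on log-abundance with per-branch
variance s * branch_length, so s = 0 gives identical lineage profiles
(no phylosymbiosis) and s = 1 makes community dissimilarity track host
phylogenetic distance. Per-sample compositions are Dirichlet draws around
the lineage profile and reads are multinomial at the sample's depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import GenotypeMatrix, GroupingMap, OtuTable, parse_lineage
from .phylosymbiosis import robinson_foulds
from .tree_inference import neighbor_joining, snp_pdistance

logger = logging.getLogger("phylosym")


@dataclass
class SimulationConfig:
    """Study-scale defaults: 5 lineages x (10,10,10,9,10) samples, 2,000
    OTUs, 5,000 SNP sites, log-normal depths around ~20k reads."""

    n_lineages: int = 5
    samples_per_lineage: int | Sequence[int] = (10, 10, 10, 9, 10)
    n_otus: int = 2000
    n_snp_sites: int = 5000
    n_individuals_per_lineage: int = 3
    depth_log_mean: float = np.log(20_000)   # log-scale mean of sample depth
    depth_log_sigma: float = 0.4             # log-scale sd (uneven depths)
    phylosymbiosis_effect: float = 1.0       # s in [0, 1]
    dirichlet_concentration: float = 500.0   # within-lineage dispersion
    base_log_sd: float = 1.0                 # spread of root log-abundances
    latent_scale: float = 0.3                # softmax temperature on the latent field
    mutation_scale: float = 0.5              # SNP flip rate per unit branch
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    # each planted effect: (otu_id, lineage_label, log2 fold change)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phylosymbiosis_effect <= 1.0:
            raise ValueError("phylosymbiosis_effect must be in [0, 1]")
        for name in ("n_lineages", "n_otus", "n_snp_sites", "n_individuals_per_lineage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def sample_counts(self) -> list[int]:
        if isinstance(self.samples_per_lineage, int):
            return [self.samples_per_lineage] * self.n_lineages
        counts = list(self.samples_per_lineage)
        if len(counts) != self.n_lineages:
            # an explicit layout only applies at its own lineage count
            return [counts[0]] * self.n_lineages
        return counts

    def lineage_labels(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lineages)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded with every generated dataset."""

    host_newick: str
    effect: float
    lineage_log_profiles: dict[str, list[float]]
    planted_effects: list[tuple[str, str, float]]
    seed: int

    def to_json(self, path) -> None:
        obj = asdict(self)
        obj["lineage_log_profiles"] = {
            k: [round(float(x), 6) for x in v] for k, v in self.lineage_log_profiles.items()
        }
        Path(path).write_text(json.dumps(obj, indent=2))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def generate_host_tree(n_lineages: int, seed: int | np.random.Generator = 0) -> TreeNode:
    """Pure-birth (Yule) tree on leaves L1..Ln, rescaled to unit mean branch
    length.

    Standard Yule simulation: starting from two lineages, wait an
    exponential time with rate k (k = current lineage count, unit speciation
    rate), split a uniformly chosen lineage, and stop at n; all tips end at
    the present, so the tree is ultrametric — lineages are contemporaneous,
    as real host lineages are.
    """
    if n_lineages < 3:
        raise ValueError("need at least 3 lineages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    birth = [0.0, 0.0]          # time each extant lineage was born
    parents = [TreeNode(), TreeNode()]
    root = TreeNode(children=list(parents))
    t = 0.0
    while len(parents) < n_lineages:
        k = len(parents)
        t += float(rng.exponential(1.0 / k))
        i = int(rng.integers(k))
        node = parents[i]
        node.length = t - birth[i]
        kids = [TreeNode(), TreeNode()]
        node.extend(kids)
        parents[i] = kids[0]
        birth[i] = t
        parents.append(kids[1])
        birth.append(t)
    t += float(rng.exponential(1.0 / n_lineages))  # time to the present
    order = rng.permutation(n_lineages)
    for i, tip in enumerate(parents):
        tip.length = t - birth[i]
        tip.name = f"L{int(order[i]) + 1}"
    lengths = [nd.length for nd in root.traverse(include_self=False)]
    scale = float(np.mean(lengths))
    for nd in root.traverse(include_self=False):
        nd.length /= scale
    return root


def generate_otu_tree(n_otus: int, seed: int | np.random.Generator = 0) -> TreeNode:
    """Random coalescent-topology tree over OTU labels with i.i.d.
    exponential(1) branch lengths: random pairs merge until one lineage
    remains; all branch lengths are strictly positive."""
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [TreeNode(name=f"OTU{i + 1}") for i in range(n_otus)]
    while len(nodes) > 1:
        k = len(nodes)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        del nodes[j]
        del nodes[i]
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        nodes.append(TreeNode(children=[b, a]))
    root = nodes[0]
    for child in root.children:
        if child.length is None:
            child.length = float(rng.exponential(1.0))
    return root


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def _branch_lengths_or_one(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0


def simulate_snps(
    host: TreeNode,
    n_sites: int = 5000,
    mutation_scale: float = 0.5,
    n_individuals_per_lineage: int = 3,
    seed: int = 0,
    het_noise: float = 0.01,
    max_retries: int = 10,
) -> GenotypeMatrix:
    """Evolve biallelic sites down the host tree and sample individuals.

    Each site's ancestral allele (0/1) flips along every branch with
    probability (1 - exp(-mu * branch_length)) / 2 (a two-state symmetric
    model, so the flip probability saturates at 1/2). Individuals carry
    their lineage's diploid dosage (0 or 2) except for rare heterozygous
    within-lineage noise at rate ``het_noise`` per site. Generation asserts
    that neighbor joining on the allele-sharing p-distance of the output
    recovers the host topology (RF = 0 on lineage-pooled distances) and
    redraws up to ``max_retries`` times otherwise.
    """
    from skbio import DistanceMatrix

    host = host.copy()
    _branch_lengths_or_one(host)
    labels = sorted(t.name for t in host.tips())
    rng = np.random.default_rng(seed)
    host_rf_target = host

    for attempt in range(max_retries):
        lineage_alleles = _evolve_alleles(host, n_sites, mutation_scale, rng)
        individuals, rows = [], []
        for lab in labels:
            for k in range(n_individuals_per_lineage):
                dosage = 2.0 * lineage_alleles[lab].astype(float)
                het = rng.random(n_sites) < het_noise
                dosage[het] = 1.0
                individuals.append(f"{lab}_ind{k + 1}")
                rows.append(dosage)
        g = GenotypeMatrix(individual_ids=individuals, site_ids=[f"s{j + 1}" for j in range(n_sites)],
                           genotypes=np.array(rows))
        if mutation_scale == 0:
            return g
        # recovery check on lineage-pooled distances
        d_ind = snp_pdistance(g)
        pooled = _pool_distance(d_ind, labels, n_individuals_per_lineage)
        if len(labels) < 4:
            return g
        try:
            nj_tree = neighbor_joining(pooled)
            if robinson_foulds(nj_tree, host_rf_target) == 0:
                if attempt:
                    logger.info("simulate_snps: recovered host topology after %d retries", attempt)
                return g
        except Exception:  # degenerate distances; retry
            pass
    raise RuntimeError(
        "simulate_snps: NJ failed to recover the host topology after "
        f"{max_retries} draws; increase mutation_scale or n_sites")


def _evolve_alleles(host: TreeNode, n_sites: int, mu: float,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    root_allele = rng.integers(0, 2, size=n_sites)
    state = {id(host): root_allele}
    out: dict[str, np.ndarray] = {}
    for node in host.preorder(include_self=False):
        p_flip = 0.5 * (1.0 - np.exp(-mu * (node.length or 0.0)))
        flips = rng.random(n_sites) < p_flip
        allele = state[id(node.parent)] ^ flips
        state[id(node)] = allele
        if node.is_tip():
            out[node.name] = allele
    return out


def _pool_distance(d, labels: list[str], per: int):
    """Mean inter-lineage distance from the individual-level matrix."""
    from skbio import DistanceMatrix

    n = len(labels)
    pooled = np.zeros((n, n))
    ids = list(d.ids)
    members = {lab: [i for i, x in enumerate(ids) if x.startswith(lab + "_")] for lab in labels}
    for a in range(n):
        for b in range(a + 1, n):
            vals = [d.data[i, j] for i in members[labels[a]] for j in members[labels[b]]]
            pooled[a, b] = pooled[b, a] = float(np.mean(vals))
    return DistanceMatrix(pooled, ids=labels)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def simulate_communities(
    host: TreeNode,
    config: SimulationConfig,
    otu_tree: TreeNode,
    seed: int | None = None,
) -> tuple[OtuTable, GroupingMap, SyntheticTruth]:
    """Lineage-structured OTU table with host-tree-correlated communities.

    Latent lineage profiles evolve along the host tree as Brownian motion
    with per-branch variance s * branch_length on top of a shared root
    profile. The latent field maps to a composition through a tempered
    softmax, exp(latent_scale * x): the temperature sets the community's
    dynamic range so that a handful of OTUs cannot monopolize the
    phylogenetic signal. Planted differential effects add the stated log2
    fold change directly on the abundance scale (after tempering), so a
    planted "4-fold" shift is a literal 4-fold change in expected relative
    abundance. Per-sample compositions are Dirichlet(concentration *
    composition) and read counts are multinomial at a log-normal depth.
    """
    host = host.copy()
    _branch_lengths_or_one(host)
    labels = config.lineage_labels()
    tree_labels = sorted(t.name for t in host.tips())
    if tree_labels != sorted(labels):
        raise ValueError(f"host tree leaves {tree_labels} do not match config lineages {sorted(labels)}")
    otu_ids = [t.name for t in otu_tree.tips()]
    if len(otu_ids) != config.n_otus:
        raise ValueError("otu_tree leaf count does not match config.n_otus")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.n_otus
    s = config.phylosymbiosis_effect

    root_profile = rng.normal(0.0, config.base_log_sd, size=m)
    profiles: dict[str, np.ndarray] = {}
    state = {id(host): root_profile}
    for node in host.preorder(include_self=False):
        step_sd = np.sqrt(s * (node.length or 0.0))
        profile = state[id(node.parent)] + rng.normal(0.0, step_sd, size=m) if step_sd > 0 \
            else state[id(node.parent)].copy()
        state[id(node)] = profile
        if node.is_tip():
            profiles[node.name] = profile.copy()

    otu_index = {o: j for j, o in enumerate(otu_ids)}
    planted_shift = {lab: np.zeros(m) for lab in labels}
    for otu, lineage, log2fc in config.planted_effects:
        planted_shift[lineage][otu_index[otu]] += log2fc * np.log(2.0)

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for lab, n_samples in zip(labels, config.sample_counts()):
        log_weights = config.latent_scale * profiles[lab] + planted_shift[lab]
        base = config.dirichlet_concentration * _softmax(log_weights)
        base = np.maximum(base, 1e-8)  # Dirichlet needs strictly positive alphas
        for k in range(n_samples):
            sid = f"{lab}_s{k + 1}"
            composition = rng.dirichlet(base)
            depth = int(np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sigma)))
            depth = max(depth, 100)
            rows.append(rng.multinomial(depth, composition).astype(float))
            sample_ids.append(sid)
            assignments[sid] = lab

    taxonomy = _placeholder_taxonomy(otu_ids, rng)
    table = OtuTable(sample_ids=sample_ids, otu_ids=list(otu_ids),
                     counts=np.vstack(rows), taxonomy=taxonomy)
    truth = SyntheticTruth(
        host_newick=str(host).strip(),
        effect=s,
        lineage_log_profiles={lab: list(map(float, profiles[lab])) for lab in labels},
        planted_effects=list(config.planted_effects),
        seed=int(config.seed if seed is None else seed),
    )
    return table, GroupingMap(assignments), truth


def _placeholder_taxonomy(otu_ids: list[str], rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """Synthetic ranked lineages: OTUs share a small pool of phyla/genera so
    aggregation has something to merge."""
    n_phyla, n_genera = 20, 120
    tax = {}
    for o in otu_ids:
        p = int(rng.integers(n_phyla)) + 1
        g = int(rng.integers(n_genera)) + 1
        tax[o] = parse_lineage(
            f"k__Bacteria; p__Phylum{p:02d}; c__; o__; f__; g__Genus{g:03d}; s__")
    return tax


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig, outdir: str | Path | None = None):
    """Generate the full input bundle (host tree, SNPs, OTU tree, OTU table,
    grouping, truth); optionally write it to ``outdir`` as plain-text files
    (otu_table.tsv, otus.nwk, host.nwk, host.vcf, groups.tsv, truth.json)."""
    from .io_formats import write_grouping, write_genotypes, write_newick, write_otu_table

    rng = np.random.default_rng(config.seed)
    host = generate_host_tree(config.n_lineages, rng)
    otu_tree = generate_otu_tree(config.n_otus, rng)
    snps = simulate_snps(host, n_sites=config.n_snp_sites,
                         mutation_scale=config.mutation_scale,
                         n_individuals_per_lineage=config.n_individuals_per_lineage,
                         seed=int(rng.integers(2 ** 31)))
    table, groups, truth = simulate_communities(host, config, otu_tree,
                                                seed=int(rng.integers(2 ** 31)))
    bundle = {"host_tree": host, "otu_tree": otu_tree, "genotypes": snps,
              "otu_table": table, "groups": groups, "truth": truth}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_newick(host, outdir / "host.nwk")
        write_newick(otu_tree, outdir / "otus.nwk")
        write_genotypes(snps, outdir / "host.vcf", format="vcf")
        write_otu_table(table, outdir / "otu_table.tsv")
        write_grouping(groups, outdir / "groups.tsv")
        truth.to_json(outdir / "truth.json")
    return bundle
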