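# Methods

`phylosym` tests for **phylosymbiosis**: the pattern in which a dendrogram of
host-associated microbial community similarity parallels the host phylogeny.
The pipeline runs, in order: OTU-table quality control, alpha/beta diversity,
group-wise differential abundance, construction of the two trees being
compared (a neighbor-joining host phylogeny from SNPs and a UPGMA microbial
dendrogram from weighted UniFrac distances), and a normalized Robinson–Foulds
congruence test against a randomized-tree null. A synthetic-data generator
provides every input with controllable statistical structure, so the whole
chain is testable without any external download.

## OTU-table quality control

* **Abundance filter.** An OTU is discarded when its total count across all
  samples is *strictly less than* `min_total_fraction` × grand total
  (default `1e-5`, i.e. 0.001%). The boundary convention matters for counts
  landing exactly on the threshold: equality retains.
* **Rarefaction averaging.** Each of `reps` (default 100) replicates draws
  `depth` reads per sample *without replacement* (multivariate
  hypergeometric — true rarefaction, matching the classic QIIME-1
  `single_rarefaction` behavior). `depth="auto"` is
  `floor(0.9 × minimum sample total)`. The replicate mean is rounded to
  integers, by default half-away-from-zero (`rounding="half_even"` selects
  banker's rounding); the rounding rule is configurable because "averaged,
  rounded" admits either convention.
* **Normalization.** `v = log2(count + pseudocount)` (pseudocount 1 by
  default; zero counts must be representable), then per sample
  `(v − mean) / sd` with the *sample* standard deviation (ddof = 1). Every
  sample row therefore has mean 0 and sd 1 over the retained OTUs. A sample
  whose transformed values are constant has no z-scale and is rejected by
  name.
* **Aggregation / Venn.** Counts are summed over OTUs sharing a rank label
  (empty labels pool into `Unassigned`; grand total is conserved). Venn
  presence is any count > 0 within a group's samples — no prevalence
  threshold — and the shared fraction is core / union.

## Diversity

* **ACE** follows the Chao & Lee abundance-based coverage estimator with
  rare/abundant cutoff 10 (exposed as a parameter). When every rare OTU is a
  singleton the coverage term is zero and ACE is undefined; the function
  falls back to bias-corrected Chao1 with a logged warning, the convention of
  the classic mothur/QIIME tools.
* **Simpson** defaults to 1 − Σp² (the complement form); raw dominance and
  inverse variants are selectable.
* **Weighted UniFrac**: raw = Σ_branches b·|p_A − p_B| with p_X the fraction
  of sample X's reads descending from the branch; the normalized variant
  divides by Σ b·(p_A + p_B), bounding the result by 1. Dendrograms default
  to the **normalized** variant because it is bounded and robust to depth
  differences; `weighted` (unnormalized, the QIIME-1 script default) and
  `unweighted` are one flag away, and both weighted variants are covered by
  tests. The computation is delegated to scikit-bio; because that
  implementation validates integer counts, fractional pooled profiles are
  rescaled to integer pseudo-counts per million first (UniFrac depends only
  on relative abundances; the rounding error is ≤ 1e-6).
* Group-wise comparison of alpha diversity reuses the Tukey–Kramer machinery
  from the differential-abundance module, applied to the per-sample values.

## Differential abundance

Per taxon at a chosen rank: one-way fixed-effects ANOVA across lineages,
Tukey–Kramer studentized-range pairwise comparisons (valid for unequal group
sizes), and Benjamini–Hochberg step-up adjustment applied across the taxa of
that rank only (no pooling across ranks). Group means are reported with
SE = sd/√n on the tested scale, with relative-abundance percentages always
reported alongside. The default tested scale is the per-sample log2 z-score
(`scale="relative"` tests percentages directly); both scales appear in the
output because published tables of this kind rarely state which scale was
tested, and reporting both keeps the result interpretable either way.

Degenerate inputs follow explicit conventions: all values identical →
(F = 0, p = 1) with a warning; zero within-group variance with unequal means
→ (F = ∞, p = 0) with a warning.

**Numerical note.** The table-level driver uses a vectorized batched
implementation (pooled-variance algebra plus a cached interpolation table of
the studentized-range log-survival-function per (k, df)); scipy's per-value
quadrature for that distribution costs ~10 ms per p-value, which is
prohibitive at hundreds of taxa. The per-taxon `anova_oneway` and
`tukey_kramer` functions remain exact scipy-backed references, and a test
pins the batched path to them (1e-9 relative on ANOVA, 5e-3 on pairwise p —
interpolation error is ~1e-6 on log-sf, far below decision thresholds).

## Trees

* **SNP distance**: allele-sharing p-distance on diploid dosages,
  d(i,j) = Σ|g_i − g_j| / (2 × co-observed sites), missing sites
  pairwise-deleted. The host phylogeny is Saitou–Nei neighbor joining
  (Studier–Keppler Q-criterion, via scikit-bio); negative branch-length
  estimates are clipped to zero after estimation and logged. NJ reproduces
  additive matrices exactly, which the tests verify to 1e-9.
* **UPGMA** (average linkage, via scikit-bio; the 2-leaf case is handled
  directly) builds the microbial dendrogram; output is always rooted and
  ultrametric. Merge ties resolve deterministically by input scan order.
* **Lineage pooling**: the dendrogram compares lineages, not samples. Each
  sample is converted to relative abundances and the lineage profile is the
  per-OTU mean (median selectable) of those fractions, so deep samples do
  not dominate.
* **Jackknife supports**: each replicate rarefies every sample once to a
  fixed depth, rebuilds the (pooled) UniFrac matrix and UPGMA tree; the
  support of a master-tree clade is the fraction of replicates containing
  that clade.

## The congruence test

Bipartitions are the non-trivial splits induced by internal edges, computed
on the unrooted tree (a degree-2 root contributes its split once) and
canonicalized as the side not containing the lexicographically smallest
leaf. RF is the size of the symmetric difference of the two split sets;
normalized RF divides by |B1| + |B2| (= 2(n−3) for two binary trees), so 0
means identical topology and 1 means no shared structure. Because
RF = 2(n−3) − 2·|shared| is always even for binary trees, nRF moves in steps
of 1/(n−3): with 5 leaves the achievable values are {0, 0.5, 1}, which is
why power statements use 8 lineages. The result object records this
achievable set so small-tree p-values are read correctly.

The null draws topologies **uniformly over labeled unrooted binary
topologies** by sequential leaf addition (each of the 2k−5 insertion edges
equiprobable at step k; every topology has probability 1/(2n−5)!!). The
p-value is #{r : nRF(host, r) ≤ observed} / R — ties count as
better-or-equal — with the (k+1)/(R+1) bias-corrected variant also reported.
The null loop runs on a bitmask split representation (no tree objects); a
test asserts that the fast extractor and the TreeNode-based `bipartitions`
encode identical splits. Trees are compared unrooted by default; a
`rooted=True` mode scores the observed pair by clade-set symmetric
difference as a sensitivity analysis (the null remains topology-based).
Yule or coalescent nulls are not provided; the uniform null is the
documented choice.

## Synthetic data generator

The generator emulates the statistical shape of a multi-lineage 16S study —
it is the package's test harness, not a model of any particular dataset.

* **Host tree**: standard Yule (pure-birth) simulation with unit speciation
  rate; all tips end at the present, so the tree is ultrametric (real host
  lineages are contemporaneous), rescaled to unit mean branch length. An
  early non-ultrametric variant made clock-based recovery impossible by
  construction, which is why ultrametricity is load-bearing here.
* **OTU reference tree**: random coalescent topology with i.i.d.
  exponential(1) branch lengths. With Kingman coalescent *times* instead,
  the few root-adjacent branches are enormous and their clade-mass
  differences dominate weighted UniFrac as non-self-averaging noise; i.i.d.
  lengths let the distance self-average over many small clades.
* **SNPs**: each biallelic site's ancestral allele flips along a branch with
  probability (1 − exp(−μ·b))/2 (two-state symmetric model, saturating at
  1/2); individuals carry the lineage dosage with rare heterozygote noise
  (default 0.01/site). μ defaults to 0.5 per unit branch. Generation
  asserts that NJ on the pooled p-distance recovers the host topology and
  redraws (≤10 times) otherwise, so downstream tests never start from a
  miscalibrated genotype matrix.
* **Communities**: latent lineage profiles evolve along the host tree as
  Brownian motion with per-branch variance s·b_len (s = 0 → identical
  profiles; s = 1 → full host-tree correlation), on top of a shared root
  profile (sd 1.0). The latent field maps to a composition through a
  tempered softmax `exp(0.3·x)`: the temperature (latent_scale) sets the
  community's dynamic range so that a handful of OTUs cannot monopolize the
  phylogenetic signal — without it the exponential map concentrates nearly
  all mass on a few OTUs and weighted UniFrac between lineages is pure
  realization noise. Planted log2 fold changes are added on the abundance
  scale *after* tempering, so a planted "4-fold" shift is a literal 4-fold
  change in expected relative abundance. Per-sample compositions are
  Dirichlet(500 × composition) and reads are multinomial at a log-normal
  depth (log-mean log 20,000, log-sd 0.4 — uneven depths around a realistic
  MiSeq-scale per-sample total).
* **Default layout** mirrors a five-lineage study: samples per lineage
  (10, 10, 10, 9, 10) for n = 49; 2,000 OTUs; 5,000 SNP sites; 3 genotyped
  individuals per lineage. Taxonomy strings are synthetic placeholder
  lineages (20 phyla, 120 genera) — enough structure for aggregation, no
  resemblance to any reference database.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (chimeras, PCR bias,
sequencing error), phylogenetically autocorrelated OTU abundances (latent
changes are i.i.d. across OTUs), compositional zero-inflation beyond what
Dirichlet-multinomial induces, genuine linkage structure among SNPs (sites
are exchangeable), and environmental covariates confounded with lineage.

## Problem sizes used by the test suite

Power and calibration of the end-to-end test are evaluated at 8 lineages ×
10 samples (the study's own per-lineage depth), 2,000 OTUs, rarefaction
averaged over 10 replicates, and R = 1,000 random topologies, over 100
seeded runs per effect level: at s = 1 the test rejects (p ≤ 0.05) in
92/100 runs, at s = 0 in 3/100. Differential-abundance sensitivity (planted
4-fold shifts, 5 lineages × 10 samples, 200 OTUs) and false-discovery
control (50 null datasets) use BH q < 0.05 as the decision rule. Recovery
sweeps for the dendrogram use the generator's low-noise regime (1,000 OTUs,
concentration 5,000) as their examples prescribe. These sizes are the
package's documented evaluation conditions; all are reproducible from the
fixed seeds in the tests.

## Known limitations

* The randomization null is uniform over labeled topologies while both real
  trees are clock-like; balanced tree shapes share splits with each other
  slightly more often than uniform topologies do, making the test mildly
  anticonservative (observed size 3–7% at nominal 5% in calibration runs).
* nRF granularity at 5 leaves ({0, 0.5, 1}) makes p-values coarse; published
  intermediate values such as 0.4 on 5-leaf trees cannot arise under the
  standard unrooted convention, and the rooted clade-based mode exists
  partly to probe such discrepancies.
* VCF handling is deliberately minimal: GT field only, biallelic SNPs only,
  no phasing or quality semantics.
* ACE is undefined when all rare OTUs are singletons; the Chao1 fallback is
  a convention, not a continuity of the estimator.
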