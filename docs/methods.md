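# Methods

This note documents the statistical models behind `soiltrace`, the design of
the synthetic-study generator, the numerical choices that matter, and the
limits of what the validation suite demonstrates.

## Analysis pipeline

### Gene abundance

Per-sample gene profiles are computed in two steps from mapped-read counts
x_i and gene lengths L_i: the copy number b_i = x_i / L_i, and the relative
abundance a_i = b_i / Σ_j b_j. Counts are accepted as non-negative reals
(fractional multi-mapping weights occur with some mappers); non-integrality
is warned about, not rejected. Gene tables aggregate to KO level by summing
member genes. Genes without a KO assignment are pooled as `unassigned`,
excluded from differential testing, and the remaining relative mass is
re-closed to one — the dropped fraction is recorded per sample in the
provenance output, since re-closure is a modeling choice one might want to
audit.

### Diversity

Shannon diversity is reported in nats (natural logs); observed richness is
the count of features with positive abundance. Rarefaction is Monte-Carlo
subsampling without replacement, seeded, with an exact hypergeometric
expectation `expected_richness_hypergeometric` kept alongside as an oracle.

The Jensen–Shannon distance uses base-2 logarithms so values are bounded by
1: JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M) with M = (P+Q)/2. The divergence itself is
the default distance (common in microbiome ordination); the square root —
the true metric satisfying the triangle inequality — is available via
`sqrt=True` / `--jsd-sqrt`. Zero abundances contribute nothing through the
0·log 0 := 0 convention; no pseudocounts are added. One numerical guard
matters: halving an IEEE subnormal can make M underflow to exactly zero where
P or Q is ~1e-324, which would turn a negligible term into +inf, so the KL
terms are computed only where M > 0.

### Ordination and PERMANOVA

PCoA is classical scaling: eigendecompose −½·J·D²·J (J the centering
projector), keep axes with positive eigenvalues (relative threshold 1e-10 of
the leading eigenvalue), scale eigenvectors by √λ. Negative eigenvalues are
counted and reported but not corrected (no Lingoes/Cailliez); JSD matrices
are near-Euclidean in practice and the count is visible in the output.

PERMANOVA is single-factor: SS_total = Σ_{i<j} d²_ij / n, SS_within the
analogous per-group sum, F = (SS_between/(a−1)) / (SS_within/(n−a)), with the
permutation estimator p = (1 + #{F_perm ≥ F_obs})/(1 + N), N = 999 by
default — so the smallest reportable p is 1/(N+1). The pseudo-F agrees with
the vegan-style implementation in scikit-bio to machine precision (asserted
in the tests). Multiple factors (e.g. environment group and host identity)
are run as separate calls; no sequential partitioning or restricted
permutation strata are implemented. Note a consequence of the permutation
scheme for small balanced designs: every relabeling that reproduces the
original partition reproduces F exactly, so the floor p is only attainable
when the group sizes make such collisions negligible.

### Differential abundance

Taxa: per-feature Kruskal–Wallis (tie-corrected, scipy) across the three
groups, BH step-up q-values (statsmodels), direction = group with the largest
mean relative abundance (`tie` on exact equality, excluded from marker sets).
Screens are run on features present in at least one sample of every group;
group-unique features are reported separately rather than rank-tested, since
presence/absence structure trivially dominates a rank test. Markers are
features with q < 0.05.

KO counts: a negative-binomial likelihood-ratio test built from first
principles as a transparent, shrinkage-free analogue of count-model
differential testing. Size factors are median-of-ratios over features
positive in every sample; per-feature dispersion is method-of-moments on
normalized counts, α = max((s² − μ)/μ², 1e-8); group means are
size-factor-weighted averages; the LRT statistic divided by its degrees of
freedom is referred to F(a−1, n−a) rather than χ²(a−1) — the F reference
absorbs dispersion-estimation noise and restores near-nominal type-I error at
small n (empirically 0.057 vs 0.075 for χ² at 10 samples/group, nominal
0.05; asserted within 3 binomial SEs in the tests). No outlier filtering and
no dispersion shrinkage: power at the 4-fold effects used throughout is
already near 1, and the simple estimator keeps the test auditable.

### Reporter-Z pathway enrichment

KO p-values (the unadjusted test p-values — the Z transform assumes
uniform-null p; q-values would break calibration) map to Z = Φ⁻¹(1−p), with p
clipped to [1e-15, 1−1e-15]. A pathway with k tested member KOs scores
Z_raw = ΣZ/√k and is corrected by the background of random size-k KO sets
drawn without replacement from all tested KOs: Z_adj = (Z_raw − μ_k)/σ_k,
10,000 seeded draws by default, estimated once per distinct pathway size.
The exact SRSWOR moments are kept as an oracle. Significance is Z_adj ≥ 2
(inclusive). Each significant pathway is assigned to the group in which the
most individually significant member KOs are enriched; equal top counts give
`tie`, no significant members give `unassigned`.

### Exposure-history layer

* **Colonization**: a soil species is *established* when its relative
  abundance exceeds a detection threshold (default 0) in at least
  `min_samples` (default 1) gut samples of that group. The report carries
  three complementary quantities — the established fraction of the soil
  species count, the established species' share of soil abundance, and their
  mean share of gut abundance — because "X% relative abundance" claims are
  ambiguous between the first two. Display filtering (the 0.1% stacked-bar
  threshold) is deliberately not applied to establishment calls.
* **Migration magnitude**: per-mouse JSD between its Day-60 and Day-90
  profiles on union-aligned features; birthplace groups compared by pairwise
  Wilcoxon rank-sum with BH correction. Mice missing a timepoint are skipped
  and listed.
* **Persistence**: markers significant for the same grouping at both
  timepoints with identical direction. The fraction is reported against both
  denominators (Day-60 and Day-90 marker counts), which differ a lot when
  drift inflates the Day-90 marker set.
* **Attribution**: the share of Day-90 relative abundance on taxa already
  present in the same mouse at Day 60 — the contamination check for control
  (untransferred) animals.

## Synthetic-study generator

The generator emulates the housing-experiment design: 30 mice per group by
default, three soil environments, two thirds of each group transferred at
Day 60 (split between the two other environments), one third kept as
controls. All draws derive from one master seed through per-component RNG
streams (pools, soil, gut base, markers, attractor, per-mouse resampling,
design, KO layer, catalog, counts), so changing e.g. `n_kos` does not perturb
the taxon tables.

**Soil communities.** Environment pools of 352 (desert), 290 (forest) and
443 (steppe) species share a 140-species cosmopolitan core inside a
700-species universe. Abundances are log-normal with per-environment σ
(2.59/2.98/5.5) calibrated so the expected soil Shannon index is ≈3.2 / 2.6 /
1.4 — desert most even, steppe dominated by few taxa despite being the
richest pool.

**Gut selection.** Per environment, a colonizer subset of the pool
establishes (fractions 0.713 / 0.728 / 0.472, so 251 / 211 / 209 species):
the full core plus environment-specific minor colonizers carrying 0.1% of
gut abundance in total. The core base profile (log-normal, σ = 2.4) is
*common to all groups*; this mirrors the empirical observation that
host selection drives gut communities toward a shared composition, with
environment-unique species confined to trace abundance. It is also what
makes ground truth identifiable: among shared species, the only expected
group differences are the planted markers, so sensitivity and FDR against
truth are well defined.

**Planted markers.** 9/16/12 (desert/steppe/forest) marker species — the
field-realistic split of ~37 — are drawn from a mid-abundance band
(3·10⁻⁴–10⁻²) and multiplied by 4 in their group's expected profile. The
band keeps the weakest markers detectable while keeping the groups' total
marker mass small enough that compositional re-closure barely shifts
non-marker species (closure is the classic way relative-abundance tests leak
false positives). Markers are dealt to groups in descending abundance order
so each group carries comparable planted mass. Inter-mouse variation is
Dirichlet resampling with concentration 1000 — low inter-individual
variation, as expected for isolator-housed gnotobiotic litters under a
standardized exposure.

**Day-90 drift.** Each mouse's Day-90 expectation moves a fraction r of the
way toward a shared attractor — the steppe-associated base reshaped by a
multiplicative log-normal perturbation (σ = 1.0 taxa, 0.8 KOs) on non-marker
features, mass-preserving, representing host-driven maturation. Rates are
r = 0.30 / 0.10 / 0.40 for desert/steppe/forest: steppe least, making
"steppe communities are most stable" a planted, testable phenomenon. The
attractor is pinned to the base profile on marker features so that drift
neither erases nor fabricates marker signal; which markers survive is
controlled solely by the planted persistence fraction (0.25): per group,
that share of markers, spread evenly over the abundance ranks, keeps its
fold at Day 90 while the rest revert. Transferred mice additionally mix in
5% of the new environment's minor-colonizer profile.

**Functional layer.** 4011 KOs with a common log-normal base (σ = 1.0);
130 pathways of 8–25 member KOs, 31 of them planted as enriched with
disjoint member sets and groups assigned round-robin starting at steppe;
member KOs of a planted pathway carry the 4-fold effect in that group.
Each KO maps to 1–3 catalog genes (lengths 300–3000 bp, plus 5% unassigned
genes at small fixed copy number); expected read counts are proportional to
copy number × length at a library size of 150–250k reads, with gamma-Poisson
(negative-binomial) noise at dispersion 0.05. There is no extra per-mouse
Dirichlet layer for KOs: functional profiles of replicate gnotobiotic mice
are far more reproducible than taxonomic ones, and the NB dispersion is the
stated count noise model.

**What the generator does not emulate.** Real sequencing depth and
per-sample richness variation; taxonomic correlation structure (phylogenetic
or ecological co-occurrence); strain-level dynamics; compositional
interactions beyond closure; temporal autocorrelation beyond the single
drift step; any host covariates (sex, cage). Passing the recovery suite
therefore shows the statistics are implemented correctly and calibrated
under a realistic-but-idealized noise model — not that effect sizes of this
magnitude are detectable in arbitrary real data.

## Validation suite and problem sizes

The acceptance-level tests use fixed seeds throughout and these sizes,
chosen to make each check statistically meaningful at interactive runtimes:

* Metric axioms: 200 random profile pairs and 1000 random triples for the
  √JSD triangle inequality.
* Oracle equivalence: PERMANOVA versus full enumeration of all 720 label
  permutations at n = 6; depth-2 rarefaction versus the hypergeometric
  closed form at 5000 replicates; reporter background moments at 10,000
  draws versus exact enumeration of all size-k subsets of a 10-KO universe
  (k = 2, 3, 4), within 1%.
* Null calibration: 500 PERMANOVA replicates (18 samples, 199 permutations
  each) and 500 shuffled features for Kruskal–Wallis, each required to pass
  a Kolmogorov–Smirnov uniformity test at p > 0.01; 200 pathways of k = 10
  under uniform-null KO p-values, whose significance rate must match
  1 − Φ(2) ≈ 0.0228 within 3 binomial SEs.
* Parameter recovery: 20 generator seeds at 15 mice per group (the screening
  metrics on the first 10); planted-marker sensitivity ≥ 0.9 at FDR ≤ 0.1
  for taxa and KOs, recovered persistence within ±0.1 of planted, and the
  configured drift ordering recovered in ≥ 9 of 10 seeds.
* PCoA reconstruction: Euclidean-embeddable inputs up to 40 points,
  reproduced from coordinates within 1e-8.

`scripts/acceptance.py` runs the full design (30 mice/group, 999
permutations, 10,000 background draws) in well under a minute and emits
every headline quantity the pipeline computes.

## Known limitations

* PERMANOVA has no strata/restricted permutations, so repeated measures per
  mouse (Day 60 + Day 90 in the timepoint contrast) are treated as
  exchangeable; the reported F is descriptive of separation, the p-value
  anti-conservative under within-mouse correlation.
* The NB test's moment dispersions are noisy at very low counts; the F
  reference compensates on average but individual low-count features remain
  less reliable than shrinkage-based estimators would make them.
* `kruskal_screen` tests relative abundances directly (as is standard with
  rank tests in this field); it is not a compositional method, and strong
  closure effects from very abundant differential features can leak into
  other features' tests.
* The reporter-Z background treats KO Z-scores as exchangeable; correlated
  KOs within a sample (shared genes, linked pathways) are not modeled.
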