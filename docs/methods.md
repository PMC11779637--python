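# Methods

This note records the models implemented in `locusevo`, their assumptions,
the numerical conventions chosen where several were defensible, and what the
synthetic-data generators do and do not emulate.

## Gene-damage model

A gene in a sample is classified from three evidence channels:

- **Small variants.** A variant is damaging when its consequence is
  truncating (stopgain, stoploss, frameshift), or missense with at least 7
  damaging predictions from the annotation ensemble (`support_threshold`,
  default 7).
- **Copy number.** A gene is amplified / homozygously deleted /
  heterozygously deleted when at least 25% of its length overlaps segments
  with total CN > 2·ploidy / = 0 / = 1. The overlap denominator is the full
  genomic span by default and the exonic union when exon coordinates are
  supplied; both modes are exposed. Coordinates are 1-based inclusive at
  every file interface and 0-based half-open internally. Overlapping input
  segments on one chromosome are rejected as ambiguous rather than resolved.
- **Methylation (CDKN2A only).** β ≥ 0.3 at the TSS-proximal probe marks
  epigenetic silencing. The literature also conditions on expression being
  comparable to homozygously deleted samples; that clause is not quantified
  anywhere we could verify, so it is implemented as an optional
  expression-percentile check, disabled by default.

LoF = {damaging mutation, homozygous deletion, double hit, methylation
silencing}; heterozygous deletion alone and amplification are not LoF.
When classes co-occur the fixed precedence hom_del > double_hit >
damaging_mutation > methylation_silenced > amplified > het_del > wild_type
applies; no source states a precedence, and homozygous deletion was chosen
as the most severe because it removes both alleles outright.

9p21 group membership is non-exclusive: group 1 is any sample with CDKN2A
LoF; groups 2–4 are nested refinements (all six genes lost; MTAP+CDKN2A
lost with IFNE intact; CDKN2A-only). The shipped profiles are editable
defaults, as group definitions beyond these rules are figure-level rather
than printed.

## CCF posterior and clonality

For alt reads `a` of `d` total, purity ρ, tumor/normal copy numbers n_t,
n_n and multiplicity m, the likelihood of CCF f is Binomial(a | d, E[VAF])
with E[VAF] = ρ·m·f / (ρ·n_t + (1−ρ)·n_n), evaluated on the fixed grid
{0.01, …, 1.00} and normalized. Multiplicity defaults to the standard point
estimate m̂ = clamp(round((a/d)/ρ · (ρ·n_t + (1−ρ)·n_n)), 1, n_t); a
fixed-m mode is available since integrating over multiplicities is an
equally defensible choice. Clonal probability is the mass on grid points
strictly above 0.95 (the 0.95 point itself counts as subclonal, the only
consistent reading of a strict inequality on a discrete grid), and the call
is clonal when it exceeds 0.5.

Two consequences of this statistic are worth knowing. First, it is
deliberately conservative: a truly clonal mutation is called clonal only
when its observed VAF lands at or above expectation, so the per-mutation
clonal-call rate at CCF = 1 is ≈ 0.53 / 0.78 / 0.91 at depths 200 / 500 /
1000 (exact binomial computation, purity 1). Event-ordering power therefore
grows with depth, and the ordering summary reports unordered samples
separately rather than forcing a call. Second, only mutation records are
accepted; deletions are never assigned CCFs. A gene with several damaging
mutations is "fully clonal" only if every mutation is clonal.

## Firth-penalized progression models

`FirthLogit` maximizes l(β) + ½·log det I(β) by Newton iteration on the
hat-adjusted score U*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij with
step-halving, tolerance 1e-8 on max |Δβ|, 100 iterations. The Jeffreys
penalty keeps estimates finite under complete separation and gives the
closed form (k+½)/(n+1) for an intercept-only fit, which the tests assert.

Nested models are compared by penalized likelihood ratio. The two
penalized likelihoods must share a penalty of the same dimension to be
comparable, so the restricted model is refitted with its coefficients
constrained to the nested subspace while the penalty ½·log det I(β) is
evaluated on the *full* design — the profile-penalized-likelihood
convention. Without this the statistic inflates by ≈ log n per constrained
parameter (we measured a type-I rate of 1.0 before the correction and
0.051 at nominal 0.05 after, 3000 null replicates). The statistic is
referred to χ² with Δp degrees of freedom; progression odds are e^β and
expected counts per genotype cell are sums of fitted probabilities. The
default model is additive (TP53 + CDKN2A); an interaction flag exists
because the original model structure is not stated.

Fisher's exact test (two-sided, probability-mass convention with the 1e-7
relative tolerance, as in R), Wilcoxon rank-sum (exact null when
min(n) ≤ 10 without ties, permutation-exact with ties, otherwise normal
approximation with tie and continuity corrections), BH adjustment and the
Kaplan–Meier / log-rank machinery are delegated to scipy, statsmodels and
lifelines respectively; each is verified in the tests against hand oracles
(full hypergeometric enumeration ≤ 40 totals, rank-assignment enumeration,
an explicit observed-minus-expected log-rank calculation). The survival
screen tests each ≥5%-of-cohort co-deletion profile against the
locus-wild-type reference and flags at FDR < 0.1, skipping groups with
fewer than 2 events.

## Enrichment

Ranking uses median-of-ratios size factors and log2((mean_A + 0.5) /
(mean_B + 0.5)), a documented stand-in for a full negative-binomial DE fit;
externally computed ranked lists can be supplied instead. The enrichment
score is the weighted Kolmogorov–Smirnov running-sum extremum (hit
increment |s|^p / Σ|s|^p, miss decrement 1/(N−K), p = 1), sets restricted
to 10–500 genes present in the list. Significance is by gene-label
permutation with a fixed stream; NES divides ES by the mean |permuted ES|
of matching sign; FDR is BH across sets. On an exact tie between the
positive and negative extremum the earlier position wins (the convention is
arbitrary and only matters on exact ties). The leading edge collects hits
at or before (after, for negative ES) the extremum.

Redundancy pruning applies two pairwise rules to leading edges — rule A:
if one pathway's unique genes outnumber the shared plus the other's unique
genes, the other is removed; rule B: if the shared genes outnumber both
unique sets, the higher-FDR member is removed. The source sentences state
the rules but not the traversal, so pairs are visited in ascending-FDR
order and iterated to a fixpoint, which makes the result deterministic and
idempotent; a stricter reading of rule A (u_P > S and u_P > u_Q) is
available behind a flag. Single-sample scores rank-normalize genes within
each sample and apply the same walk with exponent 0.25 (the common ssGSEA
convention; the exact scoring variant of published immune-deconvolution
suites is not reproducible from text), then z-normalize per signature.

## Causal TF-network protocol

Step 1. Genes are z-scored; the top 50% by variance are analyzed
(lexicographic tie-break). k = round(nAG·nBpG/nGpB) with nBpG = 2,
nGpB = 30. The external biclustering program this protocol originally
wrapped is replaced by a documented lightweight equivalent: average-linkage
seeding on correlation distance refined by iterated eigengene affinity
(each round reassigns every gene to the module whose PC1 it correlates with
best, with optional bonuses for TF-target sharing and PPIN adjacency),
seeded and deterministic (seed 123, 2000 update budget). Modules are
filtered on PC1 permutation FDR ≤ 0.1 (200 within-gene sample permutations,
BH across modules — the original PC1 test is unstated), variance explained
≥ 0.32 (progressor-BE preset) or ≥ 0.25 (EAC preset), keratinization-set
Fisher p ≤ 0.01, and at least one TF with target-enrichment Fisher
p ≤ 0.01 whose expression correlates with the eigengene at |r| > 0.5 (the
source threshold is unstated; 0.5 is configurable). The TF→target network
is rank-binned mutual information with a gamma-tail permutation null at
p = 1e-8 and data-processing-inequality pruning of TF–TF–target triangles.

Step 2. For each (marker M, TF A, eigengene B) triple, five Gaussian path
models are fitted on the standardized system: causal M→A→B, reactive
M→B→A, confounded A←M→B, collider M→A←B, independence (the collider is
included for completeness and can be toggled). For these recursive models
the MLE factorizes into the DAG regressions; each model's fit is
T = (n−1)·F_ML referred to χ² with df = 3 − #free-correlation-parameters,
and its log10 p-value is the model's log-probability. The single-marker
score is log₁₀P(causal) − log₁₀P(next best); ties break toward the
alternative, making the score conservative. Significance requires the
causal model to fit best and score ≥ 0.5.

Step 3. Significant models survive only if the TF is differentially
expressed between the marker-only group and locus-wild-type samples
(FDR < 0.1), positively correlated with the target-signature score
(Spearman R > 0.5, strict, and FDR < 0.1), and contributes to ≥ 30% of the
significant models.

## Tissue phenotyping

Cells are assigned the first phenotype in the fixed priority order whose
mask overlap is ≥ 0.10 (inclusive, "at least 10%"); below threshold on
every mask they stay unassigned. Cluster-resolution selection runs an
injected clusterer (default: kNN graph + Leiden) at resolutions
{0.3, 0.5, 0.7, 0.9} with seed 123 and keeps the highest median silhouette,
ties toward the lower resolution; single-cluster resolutions are skipped.
Marker-gated abundances (e.g. CD4⁺ over CD3⁺) take intensity thresholds as
configuration, since none are printed anywhere authoritative.

## Synthetic data: what it emulates and what it does not

One global seed expands into independent per-generator streams through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(tag,))` with a fixed
integer tag per generator, so outputs are bitwise reproducible and adding a
generator never perturbs existing ones.

- **Tumor genomes.** Per-gene damage classes are drawn from configurable
  frequencies (defaults are free parameters chosen once to resemble an
  EAC-like cohort — CDKN2A loss common, double-LoF TP53+CDKN2A depleted;
  no per-class counts are published). Mutation alt reads are
  Binomial(depth, E[VAF]) at the configured true CCF; CNA segments cover
  the full span of altered genes. Not emulated: subclonal copy number,
  multi-sample phylogenies, sequencing error.
- **Progression cohorts.** Genotypes from a 4-cell frequency table;
  progression is Bernoulli(logit⁻¹(β₀ + β₁·TP53 + β₂·CDKN2A)).
- **Expression cohorts.** Negative-binomial counts (dispersion 0.1, typical
  bulk RNA-seq overdispersion) around log2 means of 9. Each module's TF
  carries the marker effect on a latent factor (sd 1.0 log2); targets
  respond to the TF's *realized* expression with slope 0.9 plus a shared
  module cofactor (sd 0.5) and idiosyncratic noise (sd 0.2); background
  genes vary with sd 0.4. Three of these choices are load-bearing and
  deliberate: (i) driving targets from observed TF expression makes the
  marker→TF→module chain hold on observables — driving them from the latent
  instead makes the eigengene a cleaner measurement of the latent than the
  TF itself and the data then genuinely support the reactive model;
  (ii) the shared cofactor keeps the eigengene from being a near-copy of
  the TF (r ≈ 0.97 without it), which would make the causal and reactive
  orderings empirically indistinguishable; (iii) the quiet background
  reflects the real situation in which a co-expressed module sits in the
  variable tail of the transcriptome — the top-50% variance filter is
  meaningless if background genes vary as much as module genes. A green
  protocol test therefore establishes orientation recovery under honest
  measurement noise, not under arbitrary background structure. Not
  emulated: batch effects, library-size gradients, gene length bias.
- **Survival cohorts.** Exponential event times scaled by group hazard
  ratios; independent exponential censoring with rate chosen so the
  expected censored fraction equals `censor_rate` (the simplest model
  sufficient for log-rank calibration and power checks).
- **Cell tables.** Overlap fractions peak at 0.6 on the true phenotype
  with half-normal background noise; marker intensities are N(5,1) on
  phenotype, N(1,0.5) off. Not emulated: spatial structure, segmentation
  artifacts.

## Known limitations

- The clonality statistic's conservatism (above) caps per-sample ordering
  sensitivity at realistic depths; cohort-level ordering fractions are the
  reliable readout.
- The module finder is a deliberately small stand-in: it preserves the
  protocol's contract (k modules, ≤ 2 modules per gene, co-expression +
  PPIN + TF-target evidence, seeded determinism) but not the full
  biclustering behavior of the original external program.
- MI-threshold calibration extrapolates a gamma tail fitted to a
  permutation null; at p = 1e-8 this is far beyond the permutation count
  and should be read as "effectively no null edges", which the null-edge
  tests confirm empirically.
- Exact Spearman permutation p-values are enumerated only for n ≤ 9; the
  t-approximation above that is standard but approximate.
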