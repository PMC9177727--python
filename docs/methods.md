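# Methods

## Allelic ratio inference

At each mutated, heterozygous locus the observed read pair (X wild-type,
Y mutant) is treated as a binomial draw in the mutant-allele fraction p,
with a conjugate Beta(a, b) prior, giving the posterior
Beta(Y + a, X + b). Three log2 ratios are derived per tumor: β (DNA,
relative mutant copy number), α (RNA, net expression imbalance), and
γ = α − β (the cis-regulatory component). The count model is the
Beta-Binomial family; at the default prior the posterior over p is the
plain conjugate Beta, and overdispersion enters only through the
simulator (see below), not the estimator.

Choices that the published description leaves open, fixed here as package
defaults:

- **Prior** — Beta(1, 1) (flat). Jeffreys Beta(0.5, 0.5) is supported via
  `PosteriorSpec`. At the ≥ 30-read depths admitted by the cohort filter
  the prior contributes ≤ ~6% of the posterior pseudo-counts, so the
  choice is immaterial at reporting precision.
- **Interval** — equal-tailed (central) credible interval, not HPD, at
  level 0.89. Equal-tailed intervals are invariant under the monotone
  log-odds transform, so p-quantiles map directly to ratio quantiles.
- **MAP** — posterior mode of p mapped through log2(p/(1−p)). A zero
  count on one allele puts the mode on the boundary; the MAP is then
  reported as a ±infinity sentinel while the CI (always interior for
  positive priors) still drives the imbalance call.
- **γ posterior** — the distribution of a difference of independent
  log-odds has no closed form. The CI comes from seeded Monte-Carlo
  (default 20,000 draws, floor 10,000; doubling the draws moves CI
  endpoints by < 0.02 log2 units at depth ≥ 30). The γ MAP is computed
  as MAP(α) − MAP(β): the mode of a difference is not in general the
  difference of modes, but at admitted depths the discrepancy is below
  reporting precision, and the difference form is exactly reproducible
  with no Monte-Carlo noise.
- **Call rule** — a ratio is imbalanced iff its CI excludes zero;
  the interval sign then separates mutant- from wild-type-preferring.

## Cohort filters

Tumors enter the analysis when the mutation is missense and the total
allelic depth (both alleles summed) is at least 30 reads in the DNA assay
and in the RNA assay at the mutated locus. The threshold applies to the
per-assay total, not per allele. A sample carrying several qualifying
missense mutations yields one profile per mutation by default; a
`keep-max-depth` collapsing mode retains only the deepest locus per
sample. Every exclusion carries a machine-readable reason code and is
logged, and filtering is idempotent.

## Variance decomposition

Because γ = α − β algebraically, Var(α) = Var(β) + Var(γ) + 2 Cov(β, γ)
holds exactly; the decomposition reconstructs α as β + γ so the identity
is true to machine precision by construction, and the informative outputs
are the component variances, the covariance, and the cis fraction
(Var(γ) + Cov(β, γ)) / Var(α). Decomposition and Pearson correlations run
on MAP point estimates (not posterior draws); samples with an infinite
MAP sentinel are excluded (variance undefined) and logged. Sample
statistics use the n − 1 denominator; cohorts need n ≥ 3 finite profiles.

## Prevalence of mutant preference

Among γ-imbalanced tumors, the count preferring the mutant allele is
tested against Binomial(n, 1/2). The two-sided P value uses the
minimum-likelihood convention (sum of outcome probabilities no larger
than the observed outcome's), and the interval is the exact
Clopper–Pearson interval at the 89% level used throughout. At the
published desk-scale counts these reproduce the printed values: 26/26
gives P ≈ 3 × 10⁻⁸ with 89% CI [0.89, 1.00]; 19/21 gives P ≈ 2 × 10⁻⁴
with CI [0.73, 0.98].

## Normal-tissue DAE analysis

Microarray allelic log ratios are log2(A) − log2(B) per channel, with
allele A/B fixed by alphabetical ordering. Variants are retained when the
mean RNA log2 allelic intensity strictly exceeds 9.5 and at least five
samples are heterozygous. The AE ratio (RNA log-ratio minus DNA
log-ratio) is defined only at heterozygotes; |AE| ≥ 0.58 (log2 of 1.5,
inclusive) flags DAE, and a variant is a daeSNP when ≥ 10% and ≥ 3 of its
heterozygotes are flagged. A two-sample t-test of RNA log ratios
(heterozygotes vs. combined homozygotes, P < 0.05) screens variants for a
genuine allelic signal.

Mapping stratifies a daeSNP's |AE| ratios by the genotype at each
candidate within ±250 kb (inclusive at both ends) and applies a one-sided
Mann–Whitney test of heterozygotes greater than combined homozygotes —
exact enumeration for small tie-free groups, normal approximation with
tie correction otherwise. Benjamini–Hochberg correction is applied per
daeSNP across its candidate window; candidates with fewer than two
samples in either stratum are skipped. The companion eQTL test is a
Wilcoxon rank-sum (two genotype groups) or Kruskal–Wallis (three) on
total expression.

## Clinical association and survival

γ calls map one-to-one onto three categories (gamma_mut, gamma_wt,
gamma_balanced). Covariate association uses Wilcoxon rank-sum with
continuity correction (two levels) or Kruskal–Wallis (more), on MAP
values, with BH adjustment per study and significance at q ≤ 0.05.
Survival uses the product-limit estimator and log-rank test via
lifelines; overall survival takes death from any cause as the event,
disease-specific survival its own flag, and subjects alive at last
contact are censored. Group medians are undefined (NaN) when a curve
never crosses 0.5. The multivariate Cox model (lifelines `CoxPHFitter`)
dummy-codes categorical covariates and the γ category with
gamma_balanced as the reference level and reports hazard ratios with
Wald 95% CIs; constant covariates, fewer than ten events, or
non-convergence raise errors rather than returning degenerate fits.

## Synthetic cohorts

The tumor-cohort generator draws, per sample, a true copy-number log-odds
β₀ (zero with probability 1 − `p_cn_imbalance`, else Normal(0,
`cn_logodds_sd`)) and a true cis log-odds γ₀ (zero with probability
1 − `p_cis_effect`, else Normal(`cis_logodds_mean`, `cis_logodds_sd`);
a positive mean plants mutant-preferring skew). DNA counts are
Beta-Binomial around logistic(β₀) and RNA counts around
logistic(β₀ + γ₀·cellularity), with negative-binomial depths
(dispersion 5) and overdispersion ρ (default 0.01). Cellularity
(default Uniform(0.6, 1)) attenuates only the RNA-side cis effect,
mimicking wild-type contamination from normal cells. ER/PR/HER2 labels
depend on γ₀ through a logistic link (0.8 log-odds per log2 unit,
pushing toward ER−/PR−/HER2+), and survival is exponential with a
configurable hazard ratio (default 2.5) for samples with γ₀ > 0,
censored uniformly over a 15-year follow-up with 80% of deaths
disease-specific.

Defaults mirror realistic breast-cancer study conditions: a 94-tumor
missense cohort (METABRIC-scale), 100× mean depth, and a 64-sample
normal-tissue microarray panel. The generator emulates the count statistics, effect
structure, and clinical linkage of real cohorts but not mutation
multiplicity, subclonality, purity estimation, RNA editing, or reference
bias — so passing tests demonstrate correctness of the inferential
machinery under the stated model, not robustness to those artifacts.

Two deliberate conditions in the verification suite:

- **Calibration and recovery runs use ρ = 0.** The estimator assumes pure
  binomial sampling; at depth ≥ 100 even ρ = 0.01 roughly doubles count
  dispersion, so nominal 89% coverage is only expected under the matched
  model. Cohort-level behavioral checks keep ρ = 0.01 and show the
  qualitative conclusions survive overdispersion.
- **Recovery runs use cellularity 1.** Cellularity attenuates the
  RNA-side effect by design, so γ₀ itself is only recoverable without
  attenuation; at default cellularity the estimable quantity is
  γ₀ × cellularity.

The microarray generator plants one causal regulatory variant (rSNP)
whose heterozygotes express the linked haplotype `daesnp_effect` log2
units higher, measured at a daeSNP in LD r² (default 0.5) with it;
haplotype phase fixes the sign of the observed AE shift, so high LD gives
a unilateral AE distribution. Unlinked noise variants (AE noise SD 0.2)
fill the panel, with one placed outside the ±250 kb window. The default
r² = 0.5 reflects the strong-but-incomplete LD regime in which mapping is
informative: as r² → 1 the candidate-homozygote stratum among daeSNP
heterozygotes empties (at r² = 0.8, equal MAFs, and 64 samples it holds
0–2 samples), and the het-vs-hom mapping contrast is structurally
unpowered regardless of effect size — a real property of LD mapping, not
of this implementation.

## Problem sizes

The verification suite runs desk-scale exact tests instantly and sizes
its simulations as: 2,000 tumors for interval calibration; 300 tumors per
depth (30/100/300) for γ recovery; 94-tumor cohorts for cohort-level
behavior; ten 250-tumor replicate cohorts for log-rank power; ten
64-sample panels for microarray recovery.

The survival-power preset (hazard ratio 3, 250 tumors, half with a cis
effect) was sized by a power analysis that accounts for two attenuation
mechanisms a naive calculation misses: classification error moves a few
baseline-hazard tumors into the inferred gamma_mut group (and vice
versa), and mixture hazards are non-proportional — high-hazard members
of a mixed group die early, shrinking the realized marginal hazard ratio
well below the per-sample value (about 2.2 realized for a per-sample
ratio of 3 under these conditions). Under the sized preset the log-rank
separation power is ~93% across replicates.

## Known limitations

- No haplotype phasing, purity/ploidy deconvolution, or multi-locus joint
  modeling; cellularity is a simulator construct only.
- The cis fraction is reported as a point value; uncertainty is not
  propagated into the decomposition.
- Genotype imputation, LD estimation from reference panels, and
  functional annotation are upstream/downstream of this package's inputs
  and outputs.
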