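# Methods

`clonalpgs` re-implements, as a tested pipeline on synthetic data, the
inference chain that links inherited polygenic variation in blood-cell
traits to selection on a somatically acquired driver mutation
(JAK2 V617F) and to the resulting myeloproliferative-neoplasm (MPN)
subtype. This note documents the models, the conventions chosen where the
design was genuinely open, the simulation conditions used by the test
suite, and the limitations of both.

## Synthetic cohort model

The generator (`synthetic_cohort`) is a pure function of a `SimTruth`
object, including its seed; derived random streams (one per operation) make
every stage independently reproducible.

**Genotypes.** Hard-call dosages for `m_variants` SNVs at allele
frequencies Uniform(`maf_range`). Each of two latent haplotype Gaussians
follows an AR(1) process (correlation `ld_rho`) along variants within
blocks of `ld_block_size`; thresholding at the frequency quantile yields
Hardy–Weinberg hard calls whose dosage LD grows with `ld_rho`. Hard calls
(not continuous dosages) are used so reference r² and the conditional-joint
selection behave as with array data. This is a parametric LD model, not a
coalescent simulation: it produces block-wise exchangeable LD, no allele-
frequency/LD coupling, and no long-range structure.

**Traits.** Additive polygenic traits with unit variance: `m_causal`
causal variants per trait, effects Normal(0, h²/m_causal) on the
standardized-dosage scale (hence Normal(0, h²/(m_causal·2f(1−f))) per
allele), plus Normal(0, 1−h²) noise. No dominance, epistasis, or shared
architecture across traits.

**Clones.** Clone acquisition is Bernoulli with
logit P = `alpha0` + `alpha1`·liability, where the liability is one
designated trait in s.d. units. `alpha1` is the causal selection effect the
MR stage should recover. Carrier clone size is logit-normal:
VAF = expit(Normal(`vaf_mu` + `vaf_gamma`·liability, `vaf_sigma`)).
Defaults: `alpha0 = logit(0.003)` (a 0.3% detectable-carrier rate, the rate
reported for a 160k-person exome cohort), `vaf_mu = −2.8` (median VAF near
0.057, matching the reported median of 0.056), `vaf_gamma = 0.5`,
`vaf_sigma = 1`, which place roughly two-thirds to three-quarters of
carriers below the 0.1 small/large cut. There is no clonal growth or age
structure: VAF is a static draw, so time-to-detection and clone dynamics
are out of scope by design.

**Diagnosis.** ET when the ET-defining trait plus `clone_boost`·VAF (for
carriers) exceeds `et_cut`; PV analogously; when both criteria fire the
label with the larger threshold exceedance wins (ties to ET,
deterministic). A fraction `mf_frac` of cases is relabelled MF — MF is
label-only, with no separate mechanism, since no replicated PGS
association with MF progression was found. Driver classes are drawn among
cases from `driver_class_probs` (JAK2het / CALR+MPL / triple-negative,
default 0.55/0.30/0.15); JAK2het cases are then coerced to carriers
(drawing a VAF where none existed) and CALR+MPL / TN cases to
non-carriers, as those classes are JAK2-negative by definition. Drawing
classes first keeps stratum proportions at their nominal values; the
coercion means final case rows are not a random subsample of the clone
process, which is exactly the ascertainment structure the stratified
analyses assume.

**Pleiotropy injection (off by default).** For estimator stress-tests, a
`pleiotropy_frac` share of the liability trait's causal variants can
receive a direct per-allele effect on clone log-odds of magnitude
`pleiotropy_scale`, oriented with the trait-increasing allele. The
orientation matters: symmetric direct effects cancel in ratio estimators,
whereas directional ones bias IVW and are absorbed by the Egger intercept.
The stress-test setting (frac 0.3, scale 0.2) was chosen from small pilot
grids so the injected bias clearly dominates sampling noise.

**Association scans.** Quantitative outcomes: exact OLS per variant via
Frisch–Waugh–Lovell residualization, vectorized across variants. Binary
outcomes: per-variant Newton–Raphson logistic fits. These are hand-rolled
for speed (the test suite runs hundreds of genome scans); both are checked
against statsmodels fits. Monomorphic or collinear variants are emitted
with missing statistics and excluded downstream. All user-facing single
regressions (multinomial, quintile, enrichment, stepwise, disease models)
go through statsmodels.

## Polygenic-score construction

`cojo_select` implements summary-statistics stepwise conditional selection
against an LD reference: starting from the smallest-p variant, add the
variant with the smallest conditional p while it stays below the threshold
(default 5×10⁻⁸), with correlations taken from the reference panel and
zeroed beyond a 10-Mb window or across chromosomes. Joint effects come from
the multiple-regression identity β_joint = R⁻¹·b on the standardized scale.
Conditional standard errors are the marginal summary SEs scaled by the
conditional factors (se² · σ²_S/denominator, σ²_S = 1 − explained
variance), so the orthogonal case reduces exactly to the marginal test;
per-variant sample-size differences are ignored — a stated simplification
appropriate to the single-cohort synthetic setting. Candidates with
reference r² > 0.9 to a selected variant are ineligible; a singular
selected-set matrix drops the last-added variant.

Scoring is allele-aware (exact match or exact swap, `2 − dosage` for
swaps; anything else skipped and counted). Standardization uses the sample
(n−1) s.d. of the full analysis cohort by default (a controls-only
reference group is available), because downstream odds ratios are "per
1 s.d.". The inverse-normal transform is rank-based, Φ⁻¹((rank−0.5)/n),
average ranks for ties, offset 0.5.

## Association layer

Clone calls split carriers at VAF 0.1 (boundary to "large"). Multinomial
logistic fits (statsmodels MNLogit, reference category "control"/"none")
report OR per s.d. with Wald 95% CIs; perfect separation and rank-deficient
designs raise rather than silently regularize. BH-FDR is the standard
step-up. Stepwise selection is bidirectional greedy AIC with name-order
tie-breaks. Note that plain AIC keeps a pure-noise predictor with
probability P(χ²₁ > 2) ≈ 0.157, so with five noise candidates the
intercept-only model is selected in only ≈42% of replicates — the test
suite asserts that derived rate, not a stricter one.

## Mendelian randomization

Instruments: genome-wide significant in the discovery cohort AND nominally
significant (p < 0.05) in the external cohort; greedy LD pruning at
r² < 0.05 keeping the smaller discovery p; allele-frequency concordance
guard (|Δf| > 0.2 vs the reference drops the variant); effect sizes from
the external cohort (avoiding winner's curse and sample overlap);
palindromic variants with MAF > 0.4 dropped at harmonization. An optional
exclusion filter removes instruments associated with the outcome
(p < 10⁻⁶), in LD (r² > 0.01) with such a variant, or within a 10-Mb window
of one.

Estimators on harmonized (bx, sx, by, sy): IVW (weighted no-intercept
regression), Egger (with intercept, bx oriented non-negative), simple and
weighted median (percentile interpolation at cumulative weight 0.5, weights
bx²/sy²) with seeded parametric-bootstrap SEs (default 1,000 draws).
Heterogeneity uses a multiplicative random-effects scale
max(1, √(Q/df)) that never deflates the fixed-effect SE; Egger inference
uses t with m−2 df. The PRESSO-style analysis simulates the null of the
leave-one-out residual sum of squares parametrically
(by* ~ Normal(bx·β_loo, sy)), Bonferroni-flags per-instrument outliers, and
compares the observed change in IVW after outlier removal against removal
of random same-size subsets (distortion test). The headline decision rule:
IVW p below the Bonferroni threshold (default 0.0042), consistent effect
direction across all four estimators, and Egger intercept p > 0.05.
Reverse-direction MR reuses the machinery with a relaxed instrument
threshold (p < 10⁻⁶).

## Variance partitioning

Quantitative traits: type-II partial R² = (RSS_without − RSS_full)/TSS with
F-tests, nonparametric case-resampling bootstrap SEs (default 1,000
replicates, rank-deficient resamples redrawn). Binary disease models:
observed-scale R² is the OLS (linear-probability) coefficient of
determination. A squared correlation between outcome and the logistic
linear predictor was considered and rejected: it is not monotone under
nesting (a fitted reduced model can out-correlate the full model), which
would make nested-model ΔR² negative. The liability transformation is
R²_liability = R²_obs · [K(1−K)/z²] · [K(1−K)/(P(1−P))] with
z = φ(Φ⁻¹(1−K)) always recomputed; it is applied to disease models only
(ET prevalence 9×10⁻⁵, PV 5.4×10⁻⁵), never to quantitative traits.
ΔR²(%) = 100·(R²_full − R²_reduced)/R²_full; the liability multiplier
cancels when both models share K and P.

## Stratified analyses

Quintile edges use the empirical quantile with lower interpolation on the
combined case+control sample; exact-edge ties go to the lower quintile, so
assignment is order-independent. Top-vs-middle-three and
bottom-vs-middle-three logistic contrasts each exclude the opposite extreme
quintile. The carrier enrichment test median-splits carriers (ties to the
low group) and reports the protection orientation — low-PGS group coded 1,
healthy carrier coded 1 — so OR > 1 means a low score protects carriers
from the disease label; the 2×2 OR carries an exact CI from inverting the
Fisher noncentral hypergeometric distribution, with a flagged
Haldane–Anscombe 0.5 correction when a margin is empty, alongside a
covariate-adjusted logistic OR.

## Problem sizes used by the tests and acceptance script

Real-data scale (340k individuals, ~7.5M SNPs) is far beyond desk scale,
so the suite works at sizes chosen to keep every estimator in its
well-behaved regime: MR parameter recovery uses 400 variants (300 causal,
h² = 0.3), n = 50,000 split 50/20/30 into discovery/external/target, with
the baseline carrier rate raised to 3% so the outcome scan sees a few
hundred carriers — preserving the order of the real outcome-GWAS case
count (~1,100) rather than its rate. The acceptance script runs the full
chain once at n = 40,000 and additionally reports the population carrier
model at the default 0.3% rate on n = 100,000. With ~70–90 instruments and
a few hundred outcome cases, IVW SEs are ≈0.1 on the log-OR scale; the
recovery criterion (within ±2 SE of the true 0.4 in ≥90% of 100 seeded
replicates) was verified under exactly these conditions.

## What passing tests do and do not show

The generator satisfies the MR exclusion restriction by construction and
produces clean two-sample separation; passing recovery tests therefore
validate the estimators and plumbing, not the identification assumptions on
real data (population structure, genetic correlation between traits,
assortative mating, selection bias, and read-depth-dependent carrier
calling are all absent). The ET/PV labels are deterministic threshold rules
on one or two traits, which makes germline contributions to diagnosis
larger and cleaner than in clinical cohorts; quantitative values such as
ΔR² shares are generator properties, not reproductions of published
cohort estimates.

## Numerical conventions

Floats serialize at 10 significant digits with fixed field order, so
seeded runs are byte-reproducible. Quantile and median ties resolve
downward everywhere. Stepwise and stepwise-like greedy searches break ties
by name order. Logistic fits treat |coefficient| > 20–30 as separation and
raise. Singular or near-singular LD submatrices (condition number > 1e8)
back off deterministically.
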