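# Methods

## Measurement model

A CpG site is identified by the 0-based position of its forward-strand
cytosine; the paired guanine sits one base downstream. Calls from the
two strands are merged by summing modified (`n_mod`), canonical
(`n_can`) and filtered (`n_filt`) counts per site. The methylation
percentage is

    % = 100 · n_mod / (n_mod + n_can)

with ambiguous/filtered calls (`n_filt`) excluded from both numerator
and denominator, and the value missing when the unambiguous depth is
zero. Depth for all depth thresholds means `n_mod + n_can`, not total
reads including filtered calls.

Bismark coverage files do not encode strand; their records enter the
merge with an unknown-strand sentinel and are resolved positionally (a
record at the C position is forward, at the G position reverse). With a
consistent CpG reference map this assignment is unambiguous, because no
position can be the C of one site and the G of another. Two same-strand
records at one position in one sample indicate an input-preparation
fault and raise rather than being summed.

## Filtering

Filters compose in a fixed, logged order: restrict to target amplicons,
mask cells below the depth threshold (default ≥ 100×; the boundary value
100 survives), then remove sites whose C or G coincides with a known
SNV. The SNV rule exists because a variant destroys the CpG on that
allele: in bisulfite data the variant base reads as unmethylated, and in
reads pooled over K gene copies of which k carry the variant the
apparent methylation converges to m·(K−k)/K — a pure artifact. Masked
depths are retained for reporting. Per-site call rate (fraction of
samples with a value) is reported but not enforced; downstream
regression deletes incomplete cases per site.

## Site reduction

Before testing, sites with between-sample standard deviation (n−1
denominator over non-missing cells) below 5 percentage points are
removed (strictly below; SD = 5.0 is kept). Sites correlated with
Spearman R strictly above 0.9 are then collapsed: the pairwise rule is
closed into connected components — the unique parameter-free closure;
greedy pairwise merging would give order-dependent groupings — and each
component becomes one site whose per-sample value is the unweighted mean
over non-missing members. Correlations use pairwise-complete
observations (≥ 3 pairs) because missingness is sparse (a few percent)
and listwise deletion would discard data needlessly. Collapsing is not
restricted to within-amplicon pairs. Re-collapsing an already collapsed
matrix is a no-op whenever group structure is well separated; this is
verified on the standard synthetic scenario rather than guaranteed
algebraically, since averaging can in principle create new
super-threshold correlations.

## Per-site inference

Each site is fitted by OLS with intercept:

    methylation % ~ independent variable + covariates

with default covariates age at sampling (dropped when age itself is
tested), sex (male = 0, female = 1), library size per SMN copy
(untransformed; configurable) and GQN. Encodings: SMA type 1–4 → 0–3;
presymptomatic patients carry no rank and are excluded from type
contrasts; copy numbers enter as numeric values. Carriers of an *SMN1*
copy or of the positive modifier c.859G>C are excluded before severity
analyses, as their phenotype is plausibly driven by those variants.

The reported p-value is the two-sided t test on the tested coefficient
with n − p residual df; the implementation is QR-based linear algebra
and is cross-checked in the tests against a closed-form normal-equations
oracle and against statsmodels. Benjamini–Hochberg step-up adjustment is
applied across the sites of one scan (missing p-values propagate and do
not count toward m); a site is significant when adjusted p < 0.01,
strictly. Degenerate sites are flagged rather than dropped silently:
rank-deficient designs and zero residual df yield missing results,
zero-variance responses yield estimate 0 with missing p.

For small long-read cohorts a two-group severity split is provided:
among 3-copy patients, clinical types 2b and milder form the less-severe
group and 2a and more severe the more-severe group; among 4-copy
patients the boundary moves to 3b vs 3a. Treatment response groups the
HFMSE change score at ±3 points (≤ −3 decrease, ≥ 3 increase).

## Power analysis

The general-linear-model power function uses the noncentral F
distribution: power = P(F′(u, v, λ) > F_crit(α; u, v)) with
λ = f²·(u + v + 1). `required_sample_size` solves the continuous
denominator df v* meeting the target power (power is increasing in v)
and converts df to sample size. Two conversions are supported. The
default, `"n-1"`, treats the denominator df as n − 1, the conversion in
common applied use of this power function; for the default query
(f² = 0.15, u = 4, α = 0.01, power = 0.80, v* = 113.40) it gives
n = 115. The strict OLS residual-df convention `"n-u-1"`
(n = u + v + 1) gives 119 for the same query. The returned n is minimal:
n − 1 fails the power condition under the chosen convention.

## Exploration

PCA treats samples as observations and sites as variables, centered and
(by default) unit-scaled, via SVD; component signs are fixed by making
each component's largest-magnitude loading positive so score tables are
reproducible. Sites with any missing value are dropped by default and
reported; per-site mean imputation is available behind a flag and is the
practical choice for large cohorts, where at realistic call rates nearly
every site has at least one missing cell. Clustering is agglomerative
Ward on Euclidean distances in the ward.D2 convention (input distances
not pre-squared), delegated to scipy's `linkage(method="ward")`, which
the tests verify against a brute-force Lance–Williams implementation.

## Synthetic cohort generator

The generator is the package's testbed: every operating characteristic
quoted for the pipeline is measured on its output, so its defaults are
fixed to the study conditions rather than tuned per experiment.

**Cohort.** Copy-number group sizes, male counts, SMA-type composition
per group, and per-group age-at-sampling and age-at-onset moments follow
the baseline table of a reference 365-patient bisulfite cohort
(gamma-distributed ages matching each group's mean and SD). This
deliberately reproduces the age × copy-number confound: 2-copy patients
are sampled in infancy, 4-copy patients in mid-adulthood. About 1.6% of
patients carry a modifier genotype, mirroring the 365-recruited /
359-analyzed split.

**Methylation.** Site baselines are drawn from a three-component logit
mixture (lowly methylated promoter-like sites, variable intermediate
sites, highly methylated gene body). Each cell adds logit-normal
biological noise (SD 0.4, giving realistic between-sample SDs of a few
to ~10 percentage points) and passes through a call-error layer
q = p(1−δ) + (1−p)ε with δ = 0.01 (missed modification) and ε = 0.005
(non-conversion/false call). Depths are lognormal around a median of
3000× (amplicon scale) or 30× (per-patient long-read scale), with 2% of
cells missing.

**Planted effects.** Effects are specified in percentage points per
covariate unit. Because the generative model is logistic while the
analysis regresses raw percentages, the generator calibrates each
logit-scale coefficient so that the population least-squares slope of
the expected percentage over the realized covariate values — biological
noise integrated out by Gauss–Hermite quadrature — equals the requested
value. Planted sites get near-0.5 baselines, where the logistic curve is
most linear. The planted truth is therefore exact up to the (1−δ−ε)
attenuation of the error layer, about 1.5%.

**Haplotypes and artifacts.** Each patient's copies are simulated as
phased haplotypes; each is an *SMN1*-environment copy with configurable
probability and carries the marker ALT alleles accordingly (marker
semantics: ALT indicates the annotated environment, REF the opposite;
the classifier requires unanimity across genotyped markers). CpG-
destroying SNVs are simulated in both plausible caller behaviours:
destroyed copies read as canonical (diluting pooled methylation to
m·(K−k)/K) or dropped from coverage (percentage intact, depth reduced).
Pooled per-sample counts are the exact per-site sum over haplotypes,
so strand-merge count conservation is testable end to end.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequence-level read simulation and
alignment/mapping error, batch and plate effects, cell-composition
differences between samples, spatial correlation of methylation along
the locus beyond what planted effects induce, and non-CpG methylation.
Operating characteristics measured here (type-I error, sensitivity,
slope bias) are properties of the statistical machinery under a
well-specified model, not guarantees about any particular dataset.

## Problem sizes and numerical conventions

The type-I-error study uses 100 replicate null cohorts of 200 samples ×
500 sites; parameter recovery uses one cohort of 300 samples × 121 sites
at 2000× depth with 21 planted age effects (±0.5 pp/year). The whole
suite runs in well under a minute on one core because per-site OLS is
plain QR linear algebra.

Strict inequalities are used wherever a threshold is stated as strict (p_adj < 0.01, SD < 5 removal, R > 0.9). Ties in Spearman
ranks get average ranks. BH uses a stable mergesort so equal p-values
adjust deterministically. All percentages are validated into [0, 100];
coordinates are 0-based half-open everywhere, with Bismark's 1-based
positions shifted on read. Random draws all flow from explicit seeds via
numpy Generators; identical seeds give byte-identical outputs.

## Known limitations

- The marker-SNV list that defines *SMN1*- vs *SMN2*-like environments
  is taken as input; the shipped table is a synthetic stand-in, not the
  real marker set.
- Collapsed-site depths are summarized as the mean member depth, a
  reporting convenience without statistical weight downstream.
- The per-site linear model assumes homoskedastic Gaussian residuals;
  binomial sampling noise at very low depths or percentages near 0/100
  violates this, and no beta-binomial or weighted alternative is
  provided.
- Listwise deletion per site assumes missingness unrelated to
  methylation (realistic for depth-driven missingness, not guaranteed).
- No genome-wide scale-out: the design targets hundreds of sites on one
  locus, not array- or WGBS-scale data.
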