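# Methods

## Model and rationale

The package treats heterosis as a geometric consequence of nonlinear
trait–trait relationships.  Vegetative dry mass M is taken as the
lower-level, near-additive trait; growth rate and fruit number are
higher-level traits tied to M by allometries fitted across an inbred
panel:

* growth rate: `g(M) = a·M^(b + c·log10 M)`.  The exponent varies
  linearly with log10 M, i.e. log10 g is a quadratic in log10 M; with
  c < 0 the log–log curve is concave.  The base of the logarithm in the
  exponent is 10 throughout — the fitted reference coefficients are only
  reproducible under base 10, which the noise-free refit tests confirm.
* fruit number: `f(M) = M/(a + b·M + c·M²)`, a right-skewed hump with a
  unique interior maximum at `M = √(a/c)` (≈ 109.5 mg for the reference
  accession coefficients).  A Ricker form `a·M·e^(−bM)` is available as
  the AIC competitor.

If a hybrid's mass is (near) the mid-parent mass and g is concave over
the parental interval, Jensen's inequality forces the predicted hybrid
trait above the predicted parental mean — positive NLDev_MP.  On the
descending limb of f, mass heterosis translates into *negative* fruit
heterosis.  Both sign consequences are enforced as tests.

A caveat worth stating precisely: concavity of g in *linear* space does
not hold over the entire observed mass range.  Writing t = ln M, g is
concave iff the local log–log slope b + (2c/ln10)·t lies inside
((1−√(1−8c/ln10))/2, (1+√(1−8c/ln10))/2); for the reference
coefficients this means M ≳ 12 mg.  Below that the curve is locally
steeper than linear and convex.  The concavity tests therefore assert
log–log concavity over the full range and linear-space concavity above
13 mg, and the Jensen property is asserted for parent pairs over which
g is numerically concave.

NLDev always uses the model fitted on accessions only — predicting the
hybrids from a curve the hybrids never entered.  A pooled-fit or
hybrid-fit model can be substituted for sensitivity analyses, and a
mean-of-parents additive predictor is provided as the baseline.

## Fitting

Nonlinear fits are least squares on untransformed trait values
(`scipy.optimize.curve_fit`), matching the convention that produced the
reference coefficients; the SMA analysis is separate and log10-based.
Starting values come from linearizations (quadratic polynomial of
log10 G on log10 M; ordinary regression of M/F on (1, M, M²)), with a
small multiplicative multi-start fallback; non-convergence from every
start raises a `FitError` with the last diagnostic.  Confidence
intervals are asymptotic (Wald) from the curve_fit covariance with
t(n−k) critical values.  The inverse-quadratic fit is rejected if its
denominator crosses zero inside the data range.

AIC uses the Gaussian profile form `n·ln(RSS/n) + 2(k+1)` (residual
variance counted as a parameter), dropping the `n·ln(2π)+n` constant
that cancels in every comparison; `compare_models_aic` refuses models
fitted on different n.  RSS is floored at 1e−300 so a numerically
perfect fit stays finite.

SMA regression uses the closed form slope = sign(r)·sd(y)/sd(x).  The
one-sample slope test is the standard residual-versus-axis correlation
test (t with n−2 df); when the residual axis has (numerically) zero
spread the data lie on the hypothesized line and p = 1.  The two-group
slope comparison is the large-sample z-test on log slope magnitudes
with Var(log β̂) = (1−r²)/(n−2); the likelihood-ratio variant used by
dedicated SMA software would differ only in small samples.

Sigmoid growth trajectories are 3-parameter logistic fits
`K/(1+exp(−r(t−t0)))`; the inflection t0 is the age of maximal daily
growth and K/2 the mass at inflection — the operational definition of
vegetative dry mass M in the emulated protocol.

## Heterosis measurement

MPH and BPH are computed on genotype means; for positive traits
BPH ≤ MPH algebraically (larger denominator, smaller numerator).  The
discrete classification compares each hybrid to its mid-, best- and
worst-parent values.  The hybrid's uncertainty is estimated by
bootstrap: 1,000 resamples (with replacement) of its replicate
measurements give the spread of the genotype mean, and the test
statistic is t = (mean − reference)/sd(bootstrap means) — i.e. the
bootstrap sd serves as the standard error of the hybrid mean, referred
to a t distribution with n_boot−1 df (effectively normal).  Using the
replicate df (n−1 = 3) instead would make the Bonferroni-corrected
tests powerless at n = 4, and treating the bootstrap sample as n_boot
independent observations would make them trivially significant; the
chosen form is the statistically coherent middle ground.  Two-sided vs
mid-parent, one-sided vs best (above) and worst (below); Bonferroni
over the whole family, defaulting to 3 × n_hybrids tests per trait.
Categories: below_worst, negative, additive, positive, above_best, with
exact inequalities when the replicate spread is zero and
`unclassifiable` below 2 replicates.  "Best" is the larger trait value
for all four traits; for phenology (age at reproduction) the direction
is genuinely ambiguous and can be flipped by negating the trait before
classification.

Broad-sense heritability H² = var(G)/(var(G)+var(E)) uses the one-way
random-effects method-of-moments estimator with the unbalanced-design
divisor n₀ = (N − Σnᵢ²/N)/(k−1) by default; `method="reml"` fits a
random-intercept mixed model (statsmodels MixedLM) instead.  The two
agree to well under 0.02 on the panel designs used here, and the moment
estimator is orders of magnitude faster for Monte-Carlo work.  By
default heritability is computed on whatever records are passed in —
the pipeline passes the pooled accession+hybrid table.

## Distances

Genetic distance between homozygous inbreds is the allele-count
convention: each biallelic site with different calls contributes 2
allele differences (a per-site mode is available); sites missing in
either genotype are skipped, with no rescaling by the number of sites
compared.  log10 of the count feeds the heterosis regressions;
identical pairs (count 0) are flagged NaN on the log scale and drop out
of those regressions.  Markers are pre-filtered at MAF ≥ 5% and call
rate ≥ 85%.  Top-effect marker subsets rank by |effect| with ties
broken by marker id.  Geographic distance is haversine on a sphere of
radius 6371.0088 km.  Euclidean phenotypic distance standardizes each
trait to unit variance first (raw mg/d/count axes are incommensurable);
a raw mode and the |ΔM| mass mode exist.  Heterosis~distance
regressions fit OLS on (d, d²) and report the linear-only fit
alongside; no multiplicity correction is applied across the regression
battery.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 451
accessions (2 replicates), 450 hybrids (4 replicates), genotype-level
true mass 10^N(1.6, 0.7) mg spanning roughly 1–2,000 mg, growth from
the reference accession curve with multiplicative 10^N(0, 0.05) noise
(log–log r² > 0.9, the tight-scatter regime), fruit from the
inverse-quadratic curve with 10^N(0, 0.3) noise (the loose regime,
floored at 1 fruit).  Age is *defined* as M/growth so the definitional
identity growth × age = M holds on every record; replicate jitter is
lognormal with coefficient of variation `replicate_cv` (default 0.1, a
free parameter — the emulated protocol does not report within-genotype
variance — chosen to put H² in the 0.8–0.95 band).  Hybrid true mass is
mid-parent mass × (1+δ), δ ~ N(−0.10, 0.35): the negative mean produces
the observed predominance of negative mass heterosis, and the spread
puts the significantly-heterotic fraction near 60% under the bootstrap
classifier.  Draws of δ ≤ −0.95 (impossible masses) are resampled with
a capped retry, as are any parameter configurations that drive the
trait curves non-positive.  Crucially, hybrids receive the *same*
trait~mass curves and noise as accessions (plus an optional
`hybrid_trait_dev_sd` knob for null experiments) — so any heterosis of
growth or fruit in synthetic data emerges from curvature, which is
exactly the hypothesis the pipeline is built to test.

SNP matrices are 0/1 homozygous calls whose allele frequencies follow
logistic clines along a random geographic direction (per-marker slope
~ N(0, `spatial_gradient`)), producing the positive genetic–geographic
distance correlation of real isolation-by-distance panels; there is no
linkage disequilibrium or recombination model.  Coordinates are uniform
over a Eurasian-scale window.  One integer seed drives everything;
each stage draws from a `SeedSequence`-derived substream, so equal
configurations give byte-identical tables.

What the generator does *not* emulate: genetic control of mass (masses
are drawn, not computed from the SNPs), trait-specific missingness
patterns, maternal effects, block/tray structure, and measurement-error
correlation between traits.  Passing tests therefore demonstrate that
the estimators recover the structure they assume, not that real panels
satisfy those assumptions.

Two distributional notes.  First, the mid-parent average of two
lognormal masses is necessarily narrower (and slightly higher) on the
log scale than the parent distribution, so accession and hybrid trait
distributions agree in *shape* but not scale; the distribution-equality
contract is accordingly tested on standardized log10 values.  Second,
raw-scale least squares under multiplicative lognormal noise weights
large plants heavily; the recovered mass-correction coefficient c is
slightly steeper than the generative value (median ≈ −0.17 vs −0.164 at
noise sd 0.1), faithfully reflecting the estimator the reference
analysis itself used.

## Cross-experiment harmonization

When two experiments share ≥ 3 genotypes, a two-way ANOVA (genotype ×
experiment, replicate level) tests each trait for an experiment effect;
for significant traits the correction `corrected = intercept + slope ×
observed` is calibrated by OLS of reference-experiment genotype means
on target-experiment genotype means.  Calibration on means (rather than
replicates) is the default; both are exposed since the emulated
protocol does not say which produced its printed correction.  Corrected
values ≤ 0 are flagged invalid, never silently kept.

## Problem sizes and determinism

The test suite simulates at panel scale or below (≤ 450 genotypes,
≤ 2,000 markers, 100–200 Monte-Carlo repetitions), which keeps the full
suite under half a minute while leaving every stochastic assertion with
comfortable margin; `scripts/acceptance.py` uses 200 cohorts × 450
genotypes.  All simulations and bootstraps are seeded; hypothesis-based
property tests run derandomized.

## Known limitations

* The bootstrap classifier's t-form is a pinned interpretation (see
  above); alternative readings shift the heterotic percentages.
* Wald CIs for NLS coefficients understate profile-likelihood CIs for
  strongly curved likelihoods (the scale coefficient a especially).
* The SMA two-group test is asymptotic; small-group comparisons should
  not rely on it.
* The distance module expects fully homozygous biallelic calls; no
  heterozygote or multi-allelic handling.
* No genotype-to-phenotype link in the generator: heterosis~genetic
  distance regressions on synthetic data estimate a true slope of zero.
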