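# Methods

## Background and scope

Mendelian randomization (MR) uses a genetic instrument — here a polygenic
score G, a summed weighted allele count — to estimate the causal effect of
a modifiable exposure X on an outcome Y, exploiting the fact that
genotypes are assigned at conception and are therefore unconfounded by
later environment. *Stratified* (non-linear) MR goes further: it
partitions the sample into J ordered strata of the exposure distribution
and estimates a localized average causal effect (LACE) within each
stratum, with the aim of detecting non-linear exposure-outcome
relationships.

`stratmr` implements the two stratification procedures in use, the
one-sample estimators they are combined with, the inference run across
strata, and — centrally — the two diagnostic workflows that detect when
stratum-specific estimates are artefacts of selection (collider) bias
rather than genuine non-linearity. A synthetic cohort generator supplies
data with known truth, including a selection mechanism under which the
stratified estimates are provably biased while the conventional estimate
is not.

## Stratification

**Residual method.** X is regressed on G (ordinary least squares,
optionally with covariates); the residual is the "IV-free" exposure.
Individuals are ranked by residual (stable sort, so ties keep input
order) and cut into J contiguous groups whose sizes differ by at most
one, stratum 1 holding the lowest residuals. The stratifier never
transforms the exposure; callers who want a log scale pass a transformed
column. Residual stratification is only collider-free if the
genotype-exposure effect is constant across the exposure range.

**Doubly-ranked method.** Individuals are sorted by G and divided into
K = floor(N/J) consecutive pre-strata of size J; within each pre-stratum
they are ranked by X, and the j-th ranked member of every pre-stratum is
placed in final stratum j (so N = J x K when J divides N). Every full
pre-stratum contributes exactly one member to each final stratum, which
balances the instrument across final strata without the constant-effect
assumption. When J does not divide N, the trailing partial pre-stratum
of size m < J sends its exposure-ranked members to final strata 1..m;
this keeps every individual and biases the affected stratum sizes by at
most one. Ties in G or X are broken by a random permutation drawn from
`replicate_seed`; with a continuous exposure there are no ties and the
assignment is invariant to the seed. Replicates exist to average over
tie-breaking, and are combined by Rubin's rules (below).

## Estimation

Continuous outcomes: two-stage least squares (`statsmodels` IV2SLS).
With the single instrument used throughout and no covariates this is
numerically the Wald ratio cov(G,Y)/cov(G,X); the package asserts that
identity to 1e-10 in its tests. Binary outcomes: two-stage residual
inclusion (TSRI) — stage 1 is OLS of X on G, stage 2 a logistic
regression of Y on X and the stage-1 residual; the reported beta is the
log-odds coefficient on X. The TSRI standard error is the second-stage
model-based SE, which matches common practice; a nonparametric bootstrap
was considered and not implemented because the model-based SE was
calibrated (type-I error within Monte-Carlo bounds) in all the settings
exercised here. Confidence intervals are beta +/- 1.96 se and p-values
are two-sided Wald throughout, matching the symmetric intervals these
analyses conventionally report. Degenerate exact-fit cases (zero
residual variance) report se = 0, with p defined as 0 or 1 explicitly.

## Inference across strata

*Cochran's Q*: with weights w_j = 1/se_j^2 and fixed-effect mean
theta = sum(w b)/sum(w), Q = sum w (b - theta)^2 is referred to a
chi-square with J - 1 df. Applied to the LACEs it tests homogeneity of
the causal effect; applied to the per-stratum first-stage slopes
(`constant_genetic_effect_check`) it tests the constant-genetic-effect
assumption itself.

*Trend test*: inverse-variance-weighted least squares of the stratum
betas on the stratum mean exposure. The regression is on the exposure
scale rather than the stratum index because trends are interpreted per
unit of exposure; the slope's SE is the usual WLS sandwich-free
1/sqrt(sum w (x - xbar)^2).

*Rubin's rules*: for m replicates, pooled beta is the replicate mean,
W the mean within-replicate variance, B the between-replicate sample
variance, and T = W + (1 + 1/m) B. Inference uses the normal
approximation on sqrt(T) rather than small-sample Barnard-Rubin degrees
of freedom: strata here contain hundreds to thousands of individuals and
m is 2-20, where the correction is negligible. With m = 1, B is
undefined and treated as 0. The residual method is deterministic and is
run once, never pooled.

*Logical-impossibility flag*: a warning fires when every stratum point
estimate lies on one side of zero while the whole-sample CI excludes all
of them on that side — a pattern incompatible with every estimate having
a causal interpretation, and a hallmark of stratification-induced bias.

## Diagnostics

**Negative-control outcomes.** The NCO workflow runs conventional MR and
both stratified methods (doubly-ranked pooled over m replicates, 20 by
default) of the exposure on outcomes it cannot cause — an age-like
continuous variable and a sex-like binary variable — then computes Q and
the trend. `heterogeneity_flag` is p_Q < alpha (alpha defaults to 0.05
and is configurable; it is a reporting threshold, not a claim about the
false-positive cost of acting on it), and `nonnull_strata_count` counts
strata with p < alpha. Flags are invariant to affine rescaling of the
exposure, which the tests verify.

**Strata stability.** With a repeat exposure measurement, the cohort is
stratified at each occasion (same instrument, same tie-break seed) and
memberships are cross-tabulated into a J x J transition matrix; the
diagonal of the row-normalised matrix is the per-stratum retention. If
retention is near 1/J, stratum membership is mostly measurement noise
and "the effect in those with low exposure" is not a stable label for
anyone. One replicate per occasion is used: with continuous exposures
replicates coincide, and with ties a shared seed keeps the two occasions
comparable.

## Synthetic cohorts

The generator draws, per individual: dosages Binomial(2, p_k) over 20
independent variants with frequencies spread over (0.1, 0.9); G the
weighted dosage sum with equal weights scaled so var(G) = 0.1 (the
instrument explains ~10% of exposure variance, a strong polygenic score);
a standard-normal confounder U entering X (coefficient 0.3) and both
outcomes; exposure noise sd 0.9, so X has variance ~1; an age-like NCO
N(57, 8^2) and a sex-like NCO Bernoulli(0.46), both independent of
(G, U, X) by construction; a continuous outcome linear in X and U and a
binary outcome logistic in X and U with intercept -3 (prevalence ~5%,
myocardial-infarction-like). All randomness derives from one seed
through named substreams, so equal seeds give byte-identical cohorts.

An optional `exposure_skew` parameter exponentiates the Gaussian kernel
into a right-skewed, triglyceride-like exposure (standardised back to the
original mean and variance); `tg_like_scenario` uses skew 0.8, giving a
sample skewness near 3.8.

**Repeat measurements** use a Gaussian-copula construction: the exposure
is mapped to Blom normal scores, a correlated latent normal is drawn, and
values are mapped back through the empirical exposure quantiles. The
repeat series is therefore a permutation of the observed values — the
marginal distribution is preserved exactly, even for skewed exposures —
and the latent correlation is calibrated by bisection until the realised
Pearson correlation matches the target (default 0.60, a moderate
test-retest correlation typical of serum lipids) within 5e-4.

**Selection** is a single logistic draw at cohort entry on centred
exposure, centred age, sex, and the exposure-by-sex product; an infinite
intercept disables it. Exposure and age are centred so the intercept is
the log-odds of recruitment for an average-exposure (sex = 0)
individual. Selection acts once, at recruitment: any stratum-level bias
downstream emerges from the stratified-MR methods themselves, which is
the point of the exercise.

The packaged `selection_scenario` (intercept 1.0, slope 4.0 on centred
exposure, -1.0 on sex, -2.0 on exposure x sex; ~55% recruited;
n = 80,000) was designed, by simulating over candidate coefficient sets
before any test was frozen, to exhibit the qualitative signature of
collider selection in this literature: because the two sexes' recruitment
curves rise at different rates, the selection-induced exposure-sex
association is negative where the steeper curve is still rising and
positive where it has saturated, the two regions cancelling in the whole
sample. Conventional MR of the exposure on the sex-like NCO then rejects
at close to the nominal 5% rate, while stratum-specific estimates are
strongly non-null at the exposure extremes and Cochran's Q detects
heterogeneity in essentially all residual-method runs and roughly three
quarters of doubly-ranked runs at this sample size. The coefficients are
illustrative of the mechanism, not estimates of any real cohort's
recruitment.

## What the simulations do and do not show

The generator has independent variants (no linkage disequilibrium), no
relatedness, no genotyping error, Gaussian or log-normal-like exposures,
and a one-shot selection model; real cohort selection is richer (e.g.
age- and centre-dependent response, survival). Passing tests therefore
show that the estimators are calibrated and that the diagnostic workflows
detect the selection mechanism they target — not that any particular real
analysis is unbiased, nor that real selection takes this functional form.
Empirical magnitudes (e.g. a ~39% stratum-1 retention at r = 0.60 with
J = 10 on the skewed exposure) depend on the simulated exposure
distribution and will differ for other marginals.

## Problem sizes and numerical choices

Calibration studies use 300-500 simulated cohorts of n = 10,000 with
J = 5; the selection study uses 120-200 cohorts of n = 80,000 (before
~45% attrition) with J = 10 and m = 2 doubly-ranked replicates (the
continuous exposure makes replicates coincide, so m only exercises the
pooling path); the stability study uses n = 13,500 with J = 10. These
sizes were chosen so Monte-Carlo error is small relative to the effects
being measured. Repeat-measurement calibration tolerance is 5e-4 on the
Pearson correlation (40 bisection steps maximum). Singular design
matrices are reported with the name of the collinear column; one-class
binary outcomes and separation in the second stage raise errors rather
than returning divergent estimates, and per-stratum failures are
annotated on the result instead of aborting the whole stratified
analysis.
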