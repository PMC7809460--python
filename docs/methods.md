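# Methods

This note documents the models implemented in `avimeta`, the choices made
where the methodology left room, and what the synthetic-data tests do and
do not establish.

## Effect sizes

Each data cell (species x study x immune variable x season) contributes
one standardised mean difference between the sexes, male minus female, so
positive values indicate male-biased immune measures. We use Hedges' *g*:

    d = (m_M - m_F) / s_pooled,   s_pooled^2 = ((n_M-1) s_M^2 + (n_F-1) s_F^2) / df,
    J = 1 - 3 / (4 df - 1),       g = J d,    df = n_M + n_F - 2,
    v = J^2 [ (n_M + n_F) / (n_M n_F) + d^2 / (2 (n_M + n_F)) ].

The variance is the standard large-sample (Borenstein) form scaled by
J^2; alternative variance estimators exist, and this one is fixed and
documented rather than configurable. Dispersions reported as standard
errors are converted with `SD = SE * sqrt(n)`; 95% confidence intervals
with `SD = sqrt(n) (upper - lower) / (2 delta)` where `delta` is the
two-sided 95% t quantile at `n - 1` degrees of freedom (this reproduces
the 1.96 normal limit for large n). Zero-width or inverted intervals are
rejected with an explicit error, never imputed. White-blood-cell data
are analysed as proportions of the total leukocyte count, with the H/L
ratio computed from the raw heterophil and lymphocyte counts; no arcsine
or logit transform is applied to the proportions before effect-size
computation. Cells reported for a single sex are excluded (with a logged
reason) because the contrast is undefined.

## Phylogeny

A species correlation matrix `A` is derived from a rooted, (near-)
ultrametric tree by the Brownian-motion expectation: `A_ij` is the
root-to-MRCA path length of tips i and j divided by the tree depth.
Non-ultrametric input is tolerated (the per-pair denominator becomes the
mean of the two root-to-tip depths) with a warning. When a sample of
trees is supplied, a 50% majority-rule consensus is built first: a clade
is retained iff it appears in strictly more than half of the trees, and
its branch length is the mean over the supporting trees. Remaining
polytomies are resolved by repeatedly grouping two randomly chosen
children under a new node with branch length 1e-8 (seeded, so runs are
reproducible); 1e-8 is small enough that the correlation matrix changes
by less than 1e-6 per entry. The matrix API is label-keyed, and pruning
to a variable's species set is a submatrix operation (a principal
submatrix of a unit-diagonal PSD matrix remains one).

## Multilevel meta-model

Effect sizes are modelled as

    y ~ N(X beta, V),  V = sigma2_study Zs Zs' + sigma2_phylo Zp A Zp' + diag(v_i),

with known sampling variances `v_i`. Variances are estimated by REML;
the optimiser is L-BFGS-B on the log-variance scale with three starts
(a moment-based start plus two fixed brackets) and an objective
tolerance of 1e-8; estimates below 1e-7 are reported as exactly zero
(boundary solutions). Fixed effects are the GLS solution at the optimum
with covariance `(X' V^-1 X)^-1`. Season uses cell-means coding (one
mean per season, no intercept), so each season's bias is directly
testable against zero; the overall column comes from a separate
intercept-only fit. Coefficient tests are Wald Z with normal 95% CIs
(not t-based). The omnibus season statistic QM is the Wald chi-squared
on the between-season contrast(s). Cochran's Q uses the weighted
fixed-effects-only projection (weights 1/v_i) with k - p degrees of
freedom. The I2 decomposition is

    I2_c = 100 sigma2_c / (sigma2_phylo + sigma2_study + s2),
    s2 = (k-1) sum(w) / (sum(w)^2 - sum(w^2)),  w_i = 1/v_i,

the Higgins-Thompson typical sampling variance (one of several
multilevel-I2 conventions; this is the documented choice), with
I2_total the sum of the two components. The implementation is verified
against metafor's `rma.mv` (agreement to 1e-4 on coefficients, variance
components and SEs) and against a brute-force grid search of the
restricted likelihood.

## Publication-bias and influence diagnostics

Egger's test is implemented in the moderator form: the multilevel model
is refitted with the effect-size standard error appended as a continuous
moderator and asymmetry is the Wald test of that coefficient, flagged at
p < 0.10. The classical precision-weighted regression (intercept form)
is available as an option; both test the same association. Influence
screening uses the weighted fixed-effects projection, for which
leave-one-out quantities have closed forms: the standardised deleted
residual is `e_i sqrt(w_i) / sqrt(1 - h_ii)` and the leverage is the
weighted hat value. An effect is flagged when |residual| > 3, or
|residual| > 2 with leverage above twice the average p/k; thresholds are
configurable, and the model is refitted without the flagged effects.
Published guidance on influence rules for multilevel meta-analysis is
qualitative, so the specific cutoffs here are fixed choices; the
refit pathway, not the particular flags, is the contract. Using the
fixed-effects projection (rather than the mixed model) for the screen is
deliberate: it is deterministic, closed-form and fast, at the cost of
ignoring the random-effect shrinkage.

## MCMC mixed models

The sex-by-season models have fixed effects for intercept, season
(reference: non-breeding), sex (reference: female) and their
interaction, and random intercepts for study and species (covariance
`sigma2_p A`). The H/L ratio (log-transformed) and PHA use the Gaussian
family; count-type variables use a binomial logit with an additive
latent residual as overdispersion. The sampler is blocked Gibbs: all
location effects are drawn jointly from the mixed-model equations; the
random-effect variances use inverse-gamma conditionals with parameter
expansion — each random term carries a working scale `gamma_c ~
N(0, 25^2)` sampled as an additional regression coefficient, which
implies a half-t-like prior on the effective SD and removes the sticky
behaviour near zero variance. Fixed effects get a diffuse normal prior
(variance 1e8); the Gaussian residual variance an IG(0.001, 0.001)
prior. For the binomial family, the site-wise latent values are updated
with a vectorised random-walk Metropolis step (step sizes adapted to
~44% acceptance during burn-in only, frozen afterwards), and the
latent residual variance is fixed at 1 because it is not separately
identified from the link scale. All priors are configurable through
`PriorSpec`.

Package defaults are 3 chains of 60,000 iterations (10,000 burn-in,
thin 50); the pipeline and the examples use shorter, validated chains
(a few thousand iterations) because the models here are small and mix
quickly — R-hat stays within 1.01 in the shipped configurations.
Reporting is posterior mean, equal-tailed 95% credible interval (not
HPD), pMCMC = `2 min(P(draw > 0), P(draw < 0))` floored at 2/N, the
Gelman-Rubin PSRF `sqrt((W (n-1)/n + B/n) / W)` (clamped at 1 from
below, so identical chains report exactly 1), and normalised
autocovariance profiles. Correctness is checked against a closed-form
conjugate posterior (KS distance < 0.05), the OLS limit, and
parameter-recovery simulations.

## Synthetic data

The generator emulates the structure of a comparative sex-difference
dataset: by default 41 species (a unit-depth Yule tree; the pure-birth
simulation is extended by one extra exponential waiting time at the tips
so sister species are never perfectly correlated) in 24 contiguous-clade
"families" (metadata only), 24 studies, nine immune variables, two
seasons, and ~30 cells per variable with Poisson group sizes around 15.
The male-female contrast of a cell is `theta = bias(variable, season) +
a_species + b_study` with `a ~ N(0, sigma2_phylo A)` and
`b ~ N(0, sigma2_study)`; the same variance parameters also generate
*level* effects shared by both sexes so the GLMM stage has non-trivial
random intercepts to recover. Group SDs are log-normal around a
configured scale (floored at 1e-6). Gaussian-scale variables (PHA,
haemolysis, haemagglutination) carry the bias exactly in Hedges'-g
units: individuals are drawn and summarised, so the computed effect
sizes have genuine sampling error. White blood cells are multinomial
counts over five cell types (heterophils, lymphocytes, macrophages,
eosinophils, other) with logit-scale effects and per-individual logit
noise, converted to proportions; the H/L ratio comes from the raw
counts; BKA is binomial (proportion of a per-individual trial count
killed). For count-type variables the configured bias is therefore on
the logit scale, approximately but not exactly proportional to g.
Haemolysis and haemagglutination are generated for the breeding season
only, mirroring their data situation. One root seed drives everything
through spawned sub-streams (tree, effects, cell assignment, noise), so
the same configuration is byte-identical across runs.

What the generator does *not* emulate: realistic leukocyte reference
ranges or assay units (scales are arbitrary), unbalanced reporting
conventions (every simulated cell reports both sexes with SDs),
correlated measurement of multiple variables within individuals beyond
the WBC panel, and publication censoring (bias simulations construct
censoring explicitly in the tests). Passing recovery tests therefore
demonstrates that the estimators are correct under the stated model,
not that real datasets satisfy that model.

## Problem sizes in the shipped tests

The validation suite uses desk-scale designs chosen to make the
statistical assertions sharp: 1,000 randomised effect-size cases; 20
small (k <= 8) REML instances against a two-stage brute-force grid
(coarse 0.01 sweep over [0, 2]^2, then 1e-3 resolution around the
optimum); 500 null replicates at k = 40 for Wald/QM calibration; 200
replicates at k ~ 120 for recovery of a +0.5 breeding bias with
sigma2_phylo = sigma2_study = 0.2; 250 null and 60 censored funnels for
the Egger screen; 50 nine-tree consensus samples; and 30 binomial GLMM
recoveries at 40 rows x 3 chains. The acceptance script runs the full
nine-variable chain once at the default conditions plus a 20-replicate
meta-only recovery of the injected seasonal shift.

## Known limitations

- The REML fit assumes the sampling variances v_i are known exactly, as
  is conventional; very small groups make that approximation rough.
- The Egger moderator test and the influence screen share the
  fixed-effects weighting; under extreme heterogeneity their nominal
  error rates drift (the calibration tests bound this at the shipped
  conditions).
- The binomial GLMM fixes the latent residual variance at 1; effects are
  therefore on the latent-logit scale of that convention and not
  directly comparable to models with other residual conventions.
- Consensus branch lengths are means over supporting trees; other
  summaries (median, frequency-weighted) are not implemented.
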