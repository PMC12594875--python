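# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limitations of `dietgxe`.

## The mixed ANOVA model and REML estimation

For a trait measured on individual flies from inbred line *i*, age
class *j* and diet *k*, the full model is

    y_ijk = mu + L_i + A_j + D_k + L_i:A_j + L_i:D_k + A_j:D_k
            + L_i:A_j:D_k + Rep(L_i:A_j:D_k) + e_ijk

with age, diet and their interaction fixed and all line-involving terms
plus replicate random, each term an i.i.d. Gaussian variance component.
Gaussian random effects are the only supported law — it is the
distributional assumption underlying the ANOVA framework, and the paper
trail of classical panel studies offers no basis for anything else.
Reduced models (per-diet, per-age, per-cell) use the corresponding
subset of terms.

Estimation is REML.  Rows with identical fixed- and random-effect
design are first collapsed to weighted means — an exact sufficiency
reduction in which the pooled within-group sum of squares enters the
likelihood as an independent sigma2_e chi-square stratum, and the
collapse constants are retained so log-likelihoods remain comparable
across models fitted to the same data with different random-term sets
(this is what makes the likelihood-ratio test below well defined).
The optimizer is Fisher scoring on the expected information with
analytic gradients, step halving and projection onto sigma2 >= 0,
warm-started from the balanced moment estimator when the design is
balanced, with an L-BFGS-B fallback from neutral starts otherwise.
Convergence requires a relative parameter change below 1e-10 or a
vanishing projected gradient; components pinned at zero are truncated
to exactly 0 and flagged as boundary estimates.  The asymptotic
covariance matrix of the variance components is the inverse expected
REML information at the optimum (the within-group stratum contributes
dfw/(2 sigma_e^4) to the residual entry).

On perfectly balanced designs, `anova_type3_balanced` solves the
Type-III expected-mean-square equations of the unrestricted mixed model
in closed form: E[MS_U] = sigma2_e + sum over random W containing U of
(N / #levels(W)) sigma2_W.  Negative moment solutions are reported
as-is — the function is a method-of-moments oracle, not the primary
estimator.  When the moment solution is interior, REML and the oracle
coincide; the test suite checks this to a relative 1e-6 on several
balanced designs, and the package relies on REML (never SAS-style
Type III on unbalanced data) for real fits because the moment estimator
is undefined there and can go negative.

Individual random terms are tested with a boundary-corrected REML
likelihood-ratio test: 2(l_full − l_reduced) referred to the mixture
0.5·chi2_0 + 0.5·chi2_1, the correct reference when one variance
component sits on its zero boundary under the null.  The test is
conservative; null simulations in the test suite confirm a rejection
rate at or below the nominal level.

## Heritability

Broad-sense heritability is H2 = sigma2_G / (sigma2_G + sigma2_e) with
sigma2_G the sum of all line-involving components of the fitted model.
Replicate variance enters neither numerator nor denominator; because
that convention is debatable, an alternative with sigma2_Rep folded
into the denominator is reported alongside under an explicit label.
The standard error is the delta method on (sigma2_G, sigma2_e):

    dH2/dG =  sigma2_e / (sigma2_G + sigma2_e)^2
    dH2/de = -sigma2_G / (sigma2_G + sigma2_e)^2

with the 2x2 block obtained by collapsing the REML asymptotic
covariance over the genetic terms.  Intervals are H2 ± 1.96·SE, clipped
to [0, 1] with the clipping recorded.  The suite checks the delta SE
against a parametric-bootstrap SD (within 15%) and the empirical 95% CI
coverage (within [0.90, 0.98]) at true H2 of 0.2 and 0.4 on one-way
panels of 100 lines x 10 flies.

## Cross-environment genetic correlations and the rank/scale split

The genetic correlation between the same trait in two conditions is the
plug-in ratio rho_G = cov_P(i,j) / (sigma_Li · sigma_Lj), where cov_P
is the covariance of line means over lines shared by both conditions —
the only covariance computable when different individuals are measured
in each condition — and sigma_L is the among-line SD, by default the SD
of line means (an externally supplied per-condition sigma from a
variance-component fit is accepted).  The estimator is not
range-constrained: |rho| > 1 is flagged, never clamped.  Its SE is
(1 − rho^2)/sqrt(n − 3) with n the number of shared lines, and the CI
is rho ± 1.96·SE on the raw scale.  Phenotypic correlations are
Spearman rank correlations (average ranks for ties) with the same SE
form and a Fisher-z interval, tanh(atanh(rho) ± 1.96·SE).

The G-by-E interaction variance for a condition pair splits into a
re-ranking component sigma_Li·sigma_Lj·(1 − rho_G) and a
variance-magnitude component (sigma_Li − sigma_Lj)^2 / 2; %rank is the
re-ranking share.  When rho_G = 1 and the sigmas are equal the
denominator is zero — there is no interaction to decompose — and the
result carries an explicit "no interaction" status rather than a
number.  Plug-in rho_G estimates above 1 are capped at 1 inside the
decomposition only (the reported correlation keeps its raw value).

## Survival

The diet effect on lifespan is a single-covariate Cox proportional
hazards model, lambda(t) = lambda0(t)·exp(beta·D) with D = 1 for the
restricted diet.  beta maximizes the partial likelihood by
Newton-Raphson with step halving; ties use the Breslow approximation by
default — mortality recorded at multi-day intervals produces heavy
ties, and Breslow is the simple adequate choice — with Efron behind a
flag.  The SE is the inverse square root of the observed information at
the maximum; z = beta/SE with a normal p-value.  The baseline hazard is
not estimated.  A monotone likelihood (perfect separation, e.g. all
deaths in one group before any in the other) has no finite maximizer
and raises an error.  A stratified-by-line variant (separate baseline
per line) is available behind a flag as an extension beyond the
diet-only model.

Lifespan is also analysed as a quantitative trait (line + line:diet
variance components of observed death times), which is where the
lifespan heritabilities and the cross-diet lifespan correlation come
from.  Because the hazard model omits line, its beta is the marginal
diet effect: when among-line frailty is strong, the marginal estimate
is attenuated below the conditional log-hazard ratio used by the
generator (about 0.17 vs 0.259 at frailty SD 0.9 in the packaged
config).  This is a property of proportional-hazards marginalization,
not an estimation error; the generator recovery test therefore uses
frailty 0.

## Line-mean GWAS

The response is one value per line — a line mean in one condition, or
the difference in line means between two conditions.  Regressing the
between-diet difference on dosage tests variant-by-diet interaction,
because the G-by-D variance for a trait is exactly the among-line
variance of those differences.  Wolbachia infection and the five major
inversion karyotypes are removed by least-squares residualization
first (one-hot karyotypes with the most common code as reference;
aliased columns dropped with a warning).

Relatedness control is a two-step mixed-model scan: the null model
y = mu + g + e with cov(g) = sigma2_g·K is fitted once by 1-d REML over
h2 in the eigenbasis of the genomic relationship matrix K, and each
variant is then tested by generalized least squares with that
correlation structure held fixed while the residual scale is
re-estimated per variant (t test on n − 2 df).  Holding the structure
fixed and re-estimating the scale makes the scan reduce exactly to
per-variant ordinary least squares when K = I, a property the suite
checks to 1e-8.  If the null REML puts h2 at zero the scan proceeds
under the pure-noise model and says so in the result's metadata.

K is the MAF-standardized cross-product: dosages (0/2 for a fully
inbred panel) centered at 2p and scaled by sqrt(4p(1−p)) — the dosage
SD under inbreeding — then K = ZZ'/M, giving an expected unit diagonal.
MAF is computed among the lines entering the current response and the
filter is strict (maf > 0.05); filtered variants stay in the output
flagged untested with a reason.  Thresholds are Bonferroni,
alpha / n_tested.  Manhattan and Q-Q tables (with a pointwise 95% band
from Beta(k, n+1−k) order-statistic quantiles) are emitted as data;
plotting is the caller's concern.

Calibration is validated by simulation: across 100 null scans of 200
lines x 2000 variants the p-values are uniform (KS) and the
genomic-control lambda is within [0.9, 1.1]; a variant effect sized
analytically for 50% power at the Bonferroni level is detected at that
rate within binomial error.

## Trait derivation and balancing

Locomotor activity is the sum of 10-s activity-monitor counts over the
6-h window at 23 °C (2160 bins); HKDT is (index of the last nonzero
bin) x 10 s in minutes over the 2-h window at 39 °C (720 bins).  Both
window lengths and the bin width are configurable with these defaults.
An all-zero heat series means the fly never registered activity under
heat: its HKDT is missing (with a warning), not zero, since "time of
last activity" is undefined without activity.  Flies dead before a test
day are simply absent and treated as missing, never zero.

Balancing drops rows from test ages of 25 days and later (too few
survivors for useful power) and then, per trait, removes lines that
have no surviving flies on either diet at any retained test age.  The
operation reports exactly what it removed and is idempotent.  Line
means are computed after balancing by default; the unbalanced path is a
flag away.

## The synthetic panel generator

The generator emulates a 98-line, two-diet, two-age (7 and 16 days),
three-replicate panel with fly-level Gaussian phenotypes from the full
mixed model, homozygous {0,2} genotypes with an exchangeable MAF
spectrum (uniform on [0.05, 0.5] by default), Wolbachia/inversion
covariates, activity-monitor count series, and censored lifespans.
Headline defaults are taken from the observed panel this design
mirrors: censor-category probabilities 303/1706/336/6338 out of 43,750
(escaped/stuck/trapped/sampled), a conditional diet log-hazard ratio of
0.25859, and trait cell means (dry weight 0.168–0.183 mg, HKDT
22.4–37.1 min, activity totals near 0.2 counts/bin x 2160 bins).
Variance components per trait were chosen once so broad-sense
heritabilities fall in the 0.1–0.5 range typical of these traits in
inbred fly panels; the lifespan frailty SD (0.9 on the log hazard,
Weibull(3, 24) baseline) was sized by the closed-form relation
H2 ≈ (f/k)^2 / ((f/k)^2 + CV_k^2) to put lifespan heritability near
0.4.  The packaged analysis config runs a reduced panel (50 lines, 2000
variants, 8000 survival flies) so the whole chain executes in seconds;
the generator itself takes any size.

Censoring is a competing process whose hazard is proportional to the
death hazard with ratio p/(1−p) for total censoring probability p;
under proportional hazards this gives P(censored) = p exactly and makes
censoring independent of the death time given diet, so downstream
partial-likelihood estimation is unbiased.  (An earlier design that
recorded a censored fly at a fraction of its own death time is
informative censoring and measurably biases beta — the recovery test
caught it.)  Each censored fly draws its category independently with
the relative category probabilities.

One global seed expands through `numpy.random.SeedSequence` into
independent child streams (genotypes, effects, noise, censoring,
counts, covariates), so stages can be regenerated independently and a
fixed seed gives byte-identical outputs, which the suite verifies on
the full pipeline.

What the generator does **not** emulate: linkage disequilibrium or any
genome structure (variants are exchangeable given MAF, so GWAS hits
cannot be assessed for localization), inversion biology (karyotypes are
random labels, not genotype-linked), diet biochemistry, non-Gaussian
trait distributions, and mortality-driven missingness of healthspan
measurements at the reduced scale.  Passing tests therefore demonstrate
that the estimators recover the parameters of this generating model —
correctness and calibration of the machinery — not that real panels
satisfy its assumptions.

## Numerical choices and degenerate inputs

* Variance floors: sigma2_e is bounded below by 1e-10 x var(y) so the
  covariance stays invertible; estimates below 1e-8 x var(y) are
  reported as exact zeros with a boundary flag.
* The Cox Newton iteration declares perfect separation at |beta| > 50.
* Spearman at |rho| = 1 has an infinite Fisher z; the CI endpoint is
  pinned at ±1.
* %rank clips floating-point excursions just outside [0, 100]; genuine
  out-of-range inputs (rho > 1) are the caller's flagged estimates.
* Test problem sizes (200-replicate recovery at 100 lines x 3 reps x 10
  flies, 500-draw bootstrap and coverage runs, 100-seed null scans at
  200 x 2000, 20,000-fly survival recovery) were chosen as the smallest
  designs at which the checked asymptotics are expected to hold.

## Known limitations

* Fixed effects carry Wald SEs only; no Kenward–Roger or Satterthwaite
  degrees-of-freedom machinery (fixed-effect inference is not part of
  the heritability pipeline).
* Only broad-sense heritability; no narrow-sense h2 via a genomic
  relationship decomposition of fly-level data.
* The Cox model has no frailty/random-effect variant; the stratified
  extension conditions out line rather than modelling it.
* Recorded death days are treated as exact event times; the interval
  censoring induced by multi-day mortality checks is ignored beyond the
  tie handling.
* The GWAS is single-marker: no LD pruning, clumping, gene annotation
  or permutation thresholds.
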