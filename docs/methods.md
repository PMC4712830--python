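# Methods

This note documents the models implemented in `twinmotion`, the
conventions adopted where several reasonable choices exist, what the
synthetic cohort generator does and does not emulate, and the numerical
details of estimation.

## Head-motion summary

Rigid-body realignment of an fMRI series yields, per frame, three
translations (mm) and three rotations (radians) describing the frame's
position relative to the first (reference) frame.  Parameters are read
from SPM `rp_*.txt` files (translations then rotations) or FSL `.par`
files (rotations then translations); a sanity warning fires when any
|rotation| exceeds 0.5 rad, the usual signature of degrees-in-file or a
swapped dialect.

Each frame's parameters are converted to a homogeneous transform using
the SPM composition convention, T = Translate(t) · R_x · R_y · R_z with
right-handed rotations.  The displacement between two frames with
absolute transforms T1 and T2 is the RMS displacement, over a ball of
radius R centred at x_c, induced by the relative transform:

    d = sqrt( (1/5) R^2 tr(A'A) + (t + A x_c)'(t + A x_c) ),
    [A t; 0 0] = T2 T1^{-1} - I.

Defaults: R = 80 mm; x_c = (0, 0, 0), i.e. scanner-origin coordinates
(the centre is software-specific and configurable).  The metric is
defined on T2·T1⁻¹ as written; exchanging the frames changes it only at
second order.  For a pure relative translation it reduces exactly to
|t|; in general it equals the RMS displacement of points uniform in the
ball (verified in tests against a Monte-Carlo oracle at 1e5 points).

Per-subject summary: the metric is computed between *consecutive*
frames (n−1 values) and averaged; displacement from the reference frame
is also available (`reference_series`) but the consecutive mean is the
default.  The summary is natural-log transformed to normalise
residuals; the log base is a convention, recorded in output metadata.
Zero-motion traces (which only arise synthetically) are floored at
1e-6 mm before the log, with a warning.

Exclusion flags: `gross_motion` is true when any frame exceeds 3 mm
translation or 2° rotation on any axis relative to the reference frame,
with *strict* inequality at the threshold; `sd_outlier` is true when a
subject's log summary lies more than 4 cohort standard deviations from
the cohort mean — this flag is informative only and never excludes.
The 4-sd rule is applied on the log scale; applying it on the raw scale
would be equally defensible, but the log scale is the one on which the
models operate.

## Variance-component twin models

Phenotypes of a twin pair are modelled as multivariate normal with a
structured covariance.  For p traits, each variance component X ∈
{A (additive genetic), C (shared environment), D (dominance genetic),
E (unique environment)} carries a p×p lower-triangular path matrix L_X
(Cholesky parameterization), contributing Σ_X = L_X L_X' to the
within-person covariance — positive semi-definite by construction.
The cross-twin block scales each component by its biometrical
relatedness: A is 1 in MZ pairs and 0.5 in DZ and sibling pairs
(sibling pairs are pooled with DZ throughout), D is 1 / 0.25, C is 1 in
all co-twins, E is never shared.  E is mandatory; C and D are mutually
exclusive in one model (they are not jointly identified in the
two-group twin design).

Path entries are unconstrained reals; the sign indeterminacy of the
Cholesky factor is resolved by reporting variance shares and
correlations, which are invariant to it.  Keeping the parameters
unconstrained keeps the objective smooth for the quasi-Newton
optimizer.

Optional structure:

* **Sex limitation.**  `quantitative_general` duplicates every path
  matrix per sex and adds the cross-sex genetic correlation r_g^mf,
  which multiplies the 0.5 A-relatedness in opposite-sex pairs.
  r_g^mf is fixed to 1 by default; freeing it (the qualitative test)
  requires opposite-sex pairs, without which it is pinned back to 1
  with a warning.  The female member occupies the first slot of
  opposite-sex pairs by convention.
* **Sibling contrast.**  A reciprocal interaction path s per trait:
  Σ* = (I−B)⁻¹ Σ (I−B)⁻ᵀ with B holding s on cross-member, same-trait
  positions.  s is bounded to (−0.95, 0.95); |s| ≥ 1 is outside the
  invertible regime.  The transform is applied to the covariance; at
  s = 0 it reproduces the plain likelihood bit-for-bit (tested).
  Lone twins from pairs are marginalized from the *transformed* pair
  covariance, so contrast effects propagate into their variances.
* **Group variance scaling.**  A free log-scale per listed zygosity
  group multiplies that group's total covariance, accommodating the
  variance heterogeneity observed for females from opposite-sex pairs.

Covariates enter the mean model inside the likelihood, per trait:
intercept plus linear effects of sex (M = 1), age at the
trait-appropriate assessment, wave, design, number of siblings, or the
scan-to-score interval.  Continuous covariates are centred at the
sample mean (missing covariate values are imputed at the centre);
binary codes stay on their natural scale so coefficients read as raw
offsets.  An equivalent two-stage residualization is *not* used as the
primary path — the one-step mean model matches the two-stage procedure
at reported precision while keeping the likelihood coherent under
missingness.

## Full-information likelihood and missing data

Each family contributes the −2 log multivariate-normal density of its
*observed* phenotype cells, with the implied mean vector and covariance
marginalized to that subset; singletons contribute their marginal
density.  There is no imputation and no listwise deletion — essential
for the overlapping mother-report / self-report sub-samples the design
emulates.  Families sharing a zygosity group, member-sex configuration
and missingness pattern are evaluated as one block (one small Cholesky
plus vectorized quadratic forms), and blocks with identical implied
structure share a single covariance construction per evaluation.  A
non-positive-definite implied covariance yields a large finite penalty
(1e12) rather than an exception.

Gradients are analytic: the data terms differentiate in closed form
with respect to the implied mean and covariance, and the covariance
construction supplies dΣ/dθ exactly (Cholesky-product rule, contrast
chain rule, scale chain rule).  Agreement with central finite
differences is tested to ~1e-5 relative.

The saturated (unstructured) reference model — per-class means and
variances, per-class cross-twin covariances — is implemented for
univariate traits, which covers every use the analysis makes of it
(homogeneity battery, pair correlations, covariate screen).  Classes
are declared by mode strings (per group and birth-order slot, per
group, per sex, pooled; covariances by sex-specific zygosity group,
MZ/DZ-same-sex/DZ-opposite-sex, MZ/DZ, pooled, or fixed to zero), so
each null hypothesis is a coarser class assignment.

## Estimation, tests and intervals

`fit_model` minimizes the objective by L-BFGS-B (objective tolerance
1e-12 relative, projected-gradient tolerance 1e-7, one automatic
restart if the line search stalls near a penalty wall) from a
moment-based start — Falconer-style initial shares from the observed
MZ/DZ double-entry pair correlations, sample covariances for the path
blocks — plus seeded perturbed restarts (up to five starts,
deterministic given the seed; at least three always run, and the loop
stops early once two converged starts re-find the same optimum within
1e-6, the point at which the local-optimum guard has done its job).
The best solution is returned; non-converged results are returned with
`converged=False`, never dropped.

Likelihood-ratio tests compare nested fits on the plain chi-square with
df equal to the parameter-count difference.  No boundary
(chi-bar-square) correction is applied — variance components on the
boundary make the plain LRT conservative, but raw plain-LRT p-values
are the convention this analysis follows — and no multiple-testing
adjustment is made across the battery.  Model selection (ACE/ADE vs AE
vs E) drops a component when removing it is not significantly worse at
α = 0.05.  A slightly negative LRT statistic triggers a refit of the
nested model from the full model's estimates.

Profile-likelihood confidence intervals locate the values of a
parameter or derived quantity (h², rg, re, rp) where the profiled
−2 ln L exceeds the minimum by the χ²₁ quantile (3.841 at 95%),
re-optimizing all other parameters at each probe: SLSQP with an
equality constraint in general, and a fast reparameterized path for the
univariate AE heritability (with h² fixed, only the means and the total
variance remain free).  Endpoints are located by bracketing plus
Brent's method to 1e-4; correlations are clamped to [−1, 1] and an
endpoint on the boundary is flagged one-sided.  Coverage is verified by
simulation: 95% ± 2 percentage points over 500 replicate cohorts at the
study sample size for an interior heritability.

Degenerate inputs: perfectly collinear pair data put the saturated
correlation on the singular boundary; the ML estimate then approaches
but cannot reach ±1 (the double-entry Pearson estimator returns ±1
exactly).  Zero component variance makes the corresponding cross-trait
correlation undefined; it is reported as NaN.

## Synthetic cohorts

The generator runs the model forward: per family it draws
standard-normal factor scores per component with the cross-twin
correlations above (A additionally scaled by r_g^mf in opposite-sex
pairs, including opposite-sex sibling pairs), maps them through the
(optionally sex-specific) path matrices, applies the contrast
transform, and adds mean-model effects.  Twins share age at scan;
sibling pairs differ by up to ±4 years.  Report ages add a
scan-to-rating interval drawn per rater (mother: mean 0.2 y, sd 1.2,
range ±3.9; self: mean 3.1 y, sd 1.5, range 0–7.1).  Number of
siblings is 2 + Poisson(1) clipped to [2, 7] (mean ≈ 3, sd ≈ 1); wave
and design indicators are drawn with fixed probabilities.  Singletons
are generated as full pairs from a zygosity group sampled with the
cohort's pair-count weights, with the co-twin then dropped, so lone-twin
variances match the likelihood's marginalization, including under
contrast.  Sub-sample membership (missingness) is drawn per family and
trait.  A single global seed drives one generator stream; the cohort is
reproduced exactly given the seed.

Group sizes in the presets follow the study design: the maternal
sub-sample has 95 MZ pairs (60 F / 35 M), 166 DZ-plus-sibling pairs
(48 DZF, 27 DZM, 69 opposite-sex, 22 sibling) and 149 singletons; the
self-report sub-sample 101 MZ (62/39), 178 DZ+sib (50, 30, 76, 22) and
211 singletons; the pooled head-motion sample 196 MZ, 300 DZ+sib and
149 singletons.  The female share (~63%) and the F/M/OS split within DZ
are design choices where only totals are known.

### Preset moment targets

All presets place log head motion at mean −2.62 (female, age 22),
variance 0.35², heritability 0.40, male offset ln(1.032) (+3.2% raw)
and age slope ln(0.994)/year (−0.6% raw).

Bivariate presets pair HM with one SWAN score under an AE Cholesky
whose implied moments encode the published correlation triple
(rp, rg, re) at the scale's published mean, SD and male offset:

| preset | scale | var | h² | rg | re | implied rp |
|---|---|---|---|---|---|---|
| G-MI / G-BIV-MI | maternal Inattention | 1.14² | 0.72 | 0.24 | 0.12 | 0.178 |
| G-MH / G-BIV-MH | maternal Hyperactivity-Impulsivity | 1.10² | 0.86 | 0.23 | 0.05 | 0.149 |
| G-SI | self Inattention | 0.59² | 0.12 | 0.19 | 0.07 | 0.093 |
| G-SH | self Hyperactivity-Impulsivity | 0.62² | 0.152 | 0.40 | 0.03 | 0.120 |

Maternal heritabilities are set to the published MZ pair correlations
(under AE, the A component absorbs dominance, so the MZ correlation is
the natural broad-sense target).  Self-report heritabilities are not
printed; they are *solved from the AE identity*
rp = rg·√(h²₁h²₂) + re·√(e²₁e²₂) using the published triple — the only
choice that makes the three published correlations mutually consistent,
and one that lands squarely in the attenuated range expected from the
lower test–retest reliability of self report.

`G-SEXLIM-MH` is univariate maternal Hyperactivity-Impulsivity with
sex-specific structure matching the published pair covariances: female
ACE with vA = 0.46, vC = 0.51 (from MZ/DZ covariances 0.97/0.74) and
male ADE with vA = 0.44, vD = 0.20 (from 0.64/0.27 — a male ACE
solution would need negative shared environment), vE completing a total
variance of 1.21 per sex, cross-sex genetic correlation 1.  The general
sex-limitation *fit* uses sex-specific ACE paths: C absorbs what it can
of the male dominance structure (its ML estimate sits near zero for
males) while the female covariances, which the recovery targets, are
reproduced directly.

Optional Likert discretization (9 items per scale; 7 levels for mother
report, 5 for self report; symmetric thresholds, the middle category
scoring 0) is OFF by default — the analysis treats scores as continuous
— and exists to study measurement-error attenuation; coarser scales
attenuate more, mirroring the reliability gap between raters.

**What the generator does not emulate:** non-normal trait
distributions and floor effects of real SWAN scores; selection effects
of gross-motion exclusion (phenotypes and motion files are generated
independently of the exclusion flags); autocorrelation between waves;
assortative mating; real fMRI time series (motion parameter files are
random walks with spikes, rescaled to a target mean displacement when
written alongside a cohort).  Passing recovery tests therefore shows
that the estimation machinery is unbiased and calibrated *under the
model*, not that the model describes any particular real cohort.

## Problem sizes in the checked experiments

Recovery experiments in the acceptance script use 200 replicate cohorts
per target at the study sample sizes; the test suite runs the same
checks at 30–40 replicates with tolerances widened to the Monte-Carlo
standard error of the replicate mean, plus a 500-replicate CI coverage
study and a 2000-replicate type-I-error study at reduced cohort sizes.
Empirical-moment checks on the generator use 20,000–50,000 pairs.

## Known limitations

* Saturated models are univariate; multivariate homogeneity tests are
  out of scope (the analysis needs none).
* Ordinal/threshold liability models are not implemented; Likert
  scores are analysed as continuous, as in the analysis the package
  reproduces.
* Pedigrees beyond pairs (parents, larger sibships) are not supported;
  one pair per family is enforced.
* The plain LRT for variance components on the boundary is
  conservative; the chi-bar-square mixture is deliberately not applied
  (a methodological-comparison flag would be a natural extension).
* Exactly singular phenotype data (duplicated co-twin values) sit on
  the likelihood boundary; ML correlations approach but do not reach 1.
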