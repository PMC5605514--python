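# Methods

This note documents the models, parameter choices and limitations of the
package in one place. Everything stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Demographic core

Ages follow the 23-group convention: early neonatal (0–6 days), late
neonatal (7–27 days), post-neonatal (28–364 days), 1–4 years, 5-year groups
to 90–94, and an open 95+ interval. Day-denominated widths are converted to
year units before any life table arithmetic.

Abridged life tables use the Greville/Chiang conversion
`nqx = n·nMx / (1 + (n − nax)·nMx)` for closed intervals and `qx = 1`,
`nLx = lx/Mx` for the open interval (so `ex(95) = 1/M95`). Three `nax`
rules are available: mid-interval, constant-hazard, and a Coale–Demeny-style
rule in which ages 1–4 take the mortality-dependent `4a1` coefficients
(driven by the infant death rate) and all other closed groups take the
constant-hazard value. The Coale–Demeny rule is the default; the choice
matters at the third decimal of e0 for smooth schedules (the abridged e0
agrees with brute-force fine integration of the same hazard to within 0.2%
over a hundred random Gompertz–Makeham schedules).

Annualised rates of change use the continuous-growth convention
`100·ln(v1/v0)/years`. The rounding helper rounds half away from zero,
matching the convention of printed summary tables.

## Registration completeness

Adult completeness comes from two death distribution methods on a census
pair and mean annual registered deaths:

* **Generalized growth balance.** For each exact age x, the entry rate into
  the open segment x+ minus the segment growth rate is regressed on the
  registered death rate of the segment; the slope is 1/c and the intercept
  measures relative coverage change between the censuses. The regression is
  orthogonal (total least squares) because both axes carry error.
* **Synthetic extinct generations.** The population at each age is
  reconstructed from registered deaths above that age inflated by
  age-specific growth; c is the mean ratio of reconstructed to census
  population over the trim ages.
* The **hybrid** applies the GGB coverage-change correction to the second
  census before SEG and is the headline value.

The default trim is ages 15–75; a search over candidate trims minimising
the GGB orthogonal-regression RMSE is used in the pipeline. On stable
populations with binomial undercount the hybrid recovers the truth with a
median absolute error well under 0.01; rapid mortality change (an HIV
epidemic) biases all DDM variants upward by roughly +0.05 to +0.10 — a
known limitation of the method family, partially mitigated by the trim
search.

Complete-VR classification is made at the *location* level (mean capped
hybrid across census pairs ≥ 0.95) rather than per year, because sampling
noise near the threshold would otherwise flip the estimation regime back
and forth. Per-year completeness is interpolated between census-pair
midpoints and linearly extrapolated at the ends.

## Survey estimators

**Complete birth histories.** The synthetic-cohort 5q0 uses age segments at
0, 1, 3, 6, 12, 24, 36, 48 and 60 months; children censored mid-segment by
the interview are excluded from that segment; on censoring-free data the
estimate equals the Kaplan–Meier product exactly. Sampling variance is a
leave-one-mother-out jackknife.

**Summary birth histories.** Proportions dead by maternal age group are
scaled to dated 5q0 estimates by a versioned coefficient table
(`data/sbh_coefficients.csv`). The shipped coefficients were fitted from an
analytic model — a fixed fertility age pattern and a one-parameter child
survival family with an infancy-concentrated hazard — and are stable to
about ±1% across mortality levels from 0.05 to 0.20. Time locations are
death-weighted mean years before the survey (1.2 years for mothers 15–19
up to ~18 years for 45–49).

**Sibling histories.** Respondents list their sibships; only surviving
eligible (15–49) siblings can respond, so a sibship's chance of being
reported is proportional to its survivor count S — the Gakidou–King 1/S
weight corrects this exactly (a combinatorial identity verified to 1e-12 on
an enumerated toy world). Sibships with no surviving eligible member are
unobservable; their expected contribution is added parametrically by
fitting a beta-binomial to the size-biased survivor-count distribution
(the beta-binomial allows within-sibship survival correlation, which a
plain binomial would understate) and reading off its mass at zero. A short
reporting window leaves the oldest age bands nearly empty, so band rates
are smoothed with an exposure-offset Poisson fit of log-rate on age
(Gompertz), blended with the raw rates by the deaths each band can support;
45q15 is assembled from the smoothed 5-year rates. Variance is a
delete-one-group jackknife over 30 respondent groups. The default recall
window is 15 years (three 5-year periods per survey).

**Cross-source bias adjustment** removes per-source-type additive offsets
in logit space against a reference source, matching each observation to
the nearest-in-time reference observation of the same location within ±3
years (observations are dated at period midpoints, so exact-year matching
would find almost nothing). Sources with no overlap anywhere fall back to
a pooled offset with a logged warning. In the pipeline, summary birth
histories are adjusted to complete birth histories, and sibling histories
to completeness-adjusted registration where the two overlap.

## ST-GPR

Stage 1 fits transformed observations (logit for probabilities, log for
rates and ratios) on covariates with hierarchical random effects: fixed
effects and location intercepts are estimated jointly by backfitting, the
intercepts are shrunk toward region means and regions toward zero with 5
pseudo-observations, and each region receives ridge-shrunk random slopes
(50 pseudo-observations toward the global coefficients). Stage 2 smooths
residuals with tricube time weights (bandwidth λ = 10 years) and an
own-location weight ζ = 0.75 that is additionally scaled by data density,
n/(n+25), so sparsely observed locations borrow more from their region.
Stage 3 is exact GP conditioning with a Matérn-5/2 kernel (amplitude
η = 0.25, length-scale ρ = 14 years) and heteroscedastic observation
noise; draws come from the posterior with a seeded generator and the 95%
UI is the 2.5th/97.5th percentile of draws. Kernel hyperparameters are
preset per run, not optimised.

Two numerical points deserve note. First, the GP treats its mean function
as exact, so high-frequency noise in the covariate prior would be pushed
into the posterior; the stage-2 mean is therefore smoothed with a local
*linear* tricube fit (bandwidth 5 years — local linear rather than a
running mean to avoid endpoint lag on trending series). Second,
non-sampling variance per source type is estimated from cross-source
replicate spread around a robust (running-median, then precision-weighted)
temporal reference per location, with a floor of 1e-4 on the transformed
scale; a symmetric split of cell disagreements cannot attribute noise when
only two sources observe a cell, which is why the temporal reference is
used.

Interval calibration: over 200 simulated series drawn from the model
family, the 95% UI covers the truth about 94% of the time.

## Model life table system

The empirical library holds survivorship schedules at exact ages 0, 7/365,
28/365, 1, 5, …, 110 from complete-VR location-years; schedules are
extended beyond the open age with a Gompertz hazard whose slope is
estimated from the 85–89 and 90–94 rates (a constant-hazard tail was found
to overstate extreme-age survival and inflate e0 by up to ~2.5 years at
low mortality). Standards are weighted averages of logit survivorship over
the k = 10 nearest entries in (logit 5q0, logit 45q15) space, with
multiplicative preference for entries close in the hierarchy and in time;
an entry exactly at the target from the same location-year takes weight 1.

The relational fit is the Brass logit model: for fixed slope β the
intercept α is determined in closed form by the 5q0 target, and β is found
by root-finding (or, for draw matrices, vectorised bisection) on the
achieved 45q15. The identity case (targets equal to the standard's own)
returns α = 0, β = 1 exactly, and re-measuring both summary probabilities
from the fitted life table returns the requested targets to 1e-6. With
correct targets the whole path reproduces the generating schedule's e0 to
under 0.05 years.

HIV is handled structurally: the mechanistic HIV contribution — the crude
HIV death rate spread over a relative-risk age pattern peaked at ages
25–45 (with a small vertical-transmission component under 5), scaled so
added deaths equal CDR × population — is removed from every observation
before ST-GPR, the smooth HIV-free quantity is modelled, and the average
of the covariate-based and natural-history HIV rates is overlaid on the
fitted schedules. This keeps the epidemic's fast rise and fall out of the
GP, which cannot track it with a 14-year length-scale. A safeguard floor
on the HIV-free rates is implied by clipping removed hazards at a small
positive value.

Shocks are included iff deaths per total population exceed 1e-6 or deaths
exceed 100; included deaths are converted to added rates proportional to
population by default, and the inclusion report lists exclusions with
reasons.

## Stillbirths

Observations under definitions {20, 22, 24, 26, 28 weeks, 500 g, 1000 g,
none} are multiplied by versioned scalars
(`data/stillbirth_definition_scalars.csv`) onto the ≥28-week reference;
the "none" class has its own scalar and a provenance flag. The SBR:NMR
ratio is modelled on the log scale with education and a piecewise-linear
spline in log NMR as covariates; SBR draws are the element-wise product of
ratio and NMR draws.

## SDI and expected mortality

SDI is the geometric mean of three components rescaled to [0, 1] on fixed
scales — log income per capita (default limits 250–60 000), mean years of
education at 15+ (0–17), and total fertility inverted (1.5–8.0). These
limits are package defaults chosen to span the plausible observed range;
they are configurable and not canonical. Quintile thresholds come from the
final-year SDI distribution. Expected death rates per age-sex group are GP
fits of log rate on SDI with a linear prior; fitted curves are checked for
monotone non-increase in SDI and flagged otherwise. Expected E0 draws come
from evaluating all 23 curves at a location's SDI; observed-minus-expected
differences are significant when the draw-level 95% UI excludes zero.

## The synthetic world

The generator's defaults are the study conditions: 12 locations in 3
regions over 1970–2016 — four with complete registration, six with partial
registration rising from ~0.45 to ~0.90, two survey-only — and an HIV
epidemic (peak CDR 0.006 around 2002, width 7 years) in two locations.
True mortality is a Brass-relational perturbation of a two-sex baseline
standard with smoothly declining level parameters clipped so HIV-free e0
stays in [50, 85]. Populations are projected by a closed cohort-component
model with annual steps and fertility-driven births, so registered deaths,
census age distributions and exposures satisfy the demographic accounting
identities exactly — without this the death distribution methods would be
structurally biased. Covariates (income, education, fertility) are linear
in the mortality level plus smooth autocorrelated noise, as real
covariates are themselves modelled series. Surveys run every 5 years from
1987 with 5 000 mothers (birth histories) and 6 000 respondents (sibling
histories, sampled from surviving eligible individuals so selection bias
is real); sibships carry lognormal shared frailty (σ = 0.3). Shocks follow
a Poisson process (0.05 events per location-year) with lognormal sizes.
Stillbirth observations mix definitions (45% reference, 10% unlabelled)
with 8% lognormal noise.

What the world does *not* emulate: migration, age misreporting, recall
error in survey dates, cause-of-death structure beyond the HIV overlay,
and population-size uncertainty (populations are exogenous inputs).
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under clean-but-incomplete observation processes,
not robustness to data-quality pathologies beyond those modelled.

## Problem sizes and accuracy

The default end-to-end run (12 locations × 47 years × 2 sexes, 100 draws)
completes in under a minute on one CPU. Measured on this world:

* complete-VR locations: life expectancy recovered within ~0.8 years in
  every year;
* partial-registration locations: typically within 1–2.5 years;
* survey-only and HIV-epidemic locations: typically within ~2 years in
  data-covered years, but up to 4–8 years in the years with no survey
  coverage at all (before 1977 and after 2010), where estimates rest
  entirely on covariate extrapolation. This is an information limit of the
  survey design, not of the implementation: feeding the model life table
  path the true summary parameters reproduces e0 to under 0.05 years.

Draw counts default to 100 in tests and the pipeline config; release-scale
runs can raise `n_draws` to 1000 unchanged.

## Known limitations

* DDM completeness is biased upward during rapid mortality change; the
  affected HIV locations inherit a few percent of under-adjustment in
  registration-based observations.
* The sibling Gompertz band smoother trades the thin-band zero bias for a
  mild parametric bias where the age pattern departs from log-linearity
  (epidemic humps); the cross-source bias adjustment absorbs the global
  component only.
* The SBH coefficient fixture assumes the analytic fertility/survival
  family it was fitted from; strongly different fertility schedules would
  need a refitted table (the table is a versioned input, not code).
* Uncertainty intervals are calibrated for the smoothing model family;
  systematic observation biases that survive the bias adjustment are not
  reflected in the UIs.
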