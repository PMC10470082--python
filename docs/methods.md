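# Methods

`prefmap` implements a mapping ("crosswalk") pipeline from the FACT-H&N, a
disease-specific quality-of-life questionnaire, to SF-6D health utilities,
so that quality-adjusted life years can be computed when the
preference-based instrument was not administered. This note documents the
statistical models, the synthetic-data generator, the numerical choices
and the known limitations.

## Instruments

**FACT-H&N.** Five domains — physical (PWB), social/family (SWB),
emotional (EWB), functional well-being (FWB) and the head-and-neck
concerns subscale (HNCS) — with items answered on a 0–4 ordinal scale
(0 = not at all … 4 = very much). Domain scores are item sums after
mapping reverse-worded items r → 4 − r; the total is the sum of the five
domains, higher = better. Default domain maxima (28, 28, 24, 28, 40)
follow the FACIT item counts; the reversal set is configuration-driven
rather than hard-coded, because instrument versions differ. Totals above
the nominal 0–144 range warn rather than error: published samples contain
totals of 145.

**SF-6D.** Six dimensions (physical functioning, role limitation, social
functioning, pain, mental health, vitality) with 6/4/5/6/5/5 levels —
18,000 distinct health states. A tariff (value set) assigns utility
`constant + Σ_d decrement(d, level_d) + global terms`, anchored at 1 for
full health. The package evaluates any tariff conforming to its JSON
schema. The shipped tariff is **synthetic**: it mirrors the Hong Kong
SF-6Dv1 value set's structure — floor 0.315 at the all-worst state, best
non-perfect value 0.965, monotone decrements — but its individual level
decrements are invented, because the HK coefficients are not part of this
package's sources. All tests and analyses therefore exercise the
machinery, not the HK value set itself.

## Model specifications

Five nested predictor sets shared by every family:

| id | predictors (plus intercept for direct models) |
|----|-----------------------------------------------|
| M1 | total |
| M2 | total, total² |
| M3 | pwb, swb, ewb, fwb, hncs |
| M4 | M3 + the five squared domains |
| M5 | M4 + age + gender |

Squared terms are raw squares of the unscaled scores (a `square_divisor`
knob exists because some published squared-coefficient magnitudes suggest
the original beta-mixture run rescaled them; the default leaves them
raw). Gender is coded female = 1 by default; crosswalk prediction with
published coefficients demands an explicit declaration because the
original coding is not stated anywhere.

## Estimators

**OLS** via least squares with the Gaussian log-likelihood evaluated at
the MLE variance. **Tobit** treats utility 1 as right-censoring:
`Σ_{y<1} log φ((y−xβ)/σ)/σ + Σ_{y=1} log Φ̄((1−xβ)/σ)`, maximized by BFGS
with analytic gradients from the OLS start. **Ordered probit** (used per
SF-6D dimension for response mapping) without intercept:
`P(Y ≤ j) = Φ(κ_j − xβ)` with strictly increasing cutpoints enforced by a
log-increment parametrisation; empty categories are collapsed with a
recorded level remapping so tariff level indices stay aligned.
**Beta-mixture** is a two-part model: a logit for the probability mass at
full health (fitted with a tiny L2 ridge, 1e−6, so separation — the
typical situation when only a handful of subjects are at ceiling —
degrades gracefully instead of diverging), and, conditional on y < 1, a
C-component mixture of beta densities on z = (y − L)/(U_c − L) with
logit-linked means, constant component probabilities and per-component
precisions. L defaults to the tariff floor 0.315; U_c is 1, or 0.965 for
the truncated variant that respects the infeasible gap below full
health. The reported log-likelihood includes the −n·log(U_c − L)
change-of-variable term so it lives on the utility scale.

Mixture likelihoods are multimodal, so the interior part is optimized
from 20 jittered starts (seeded, default seed 20210501); component labels
are fixed by sorting on the average fitted mean. Gradient-norm tolerance
is 1e−8 throughout; standard errors come from the inverse numeric Hessian
at the optimum (analytic for OLS).

**Parameter counts for AIC/BIC** follow the conventions of the
econometric software whose output the published tables descend from (the
printed BIC−AIC gaps identify them exactly): OLS counts only the p
regression coefficients (σ excluded), Tobit p + 1, ordered probit p +
(J−1) cutpoints summed over the six dimensions for the response mapping,
and the beta-mixture C·p + C + (C−1) + p. Direct- and indirect-model
criteria are on different likelihood scales and are only compared within
a family.

**Prediction.** OLS and Tobit predict the linear index x'β — for Tobit
deliberately the *latent* index, not the censored expectation, which is
what reproduces published predictions whose maxima exceed the OLS maxima;
the censored expectation `Φ(z)xβ − σφ(z) + Φ̄(z)·1` is available behind a
flag. The beta-mixture predicts `P(y=1) + (1−P(y=1))(L + (U_c−L)·Σ_c π_c
μ_c(x))`. The indirect (response-mapping) prediction combines the six
dimensions' level probabilities with the tariff: exactly, by enumerating
all 18,000 joint states under cross-dimension independence given
covariates; for a purely additive tariff this collapses to `constant +
Σ_d Σ_j p_dj·decrement(d,j)`, and both routes are implemented and must
agree to 1e−12.

## Model selection

Fit statistics: RMSE, MAE, the percent of absolute errors strictly above
0.05 and 0.10, Lin's concordance correlation coefficient (population
moments; the n−1 variant is a flag), AIC and BIC. The **average rank
value (ARV)** ranks each statistic across a model pool (ascending except
CCC; midranks on ties) and averages the ranks; lowest wins. Pools follow
the published structure: each of OLS/Tobit/ordered-probit over its five
specifications, all sixteen beta-mixture variants jointly. Internal
validation runs (i) fivefold cross-validation, metrics computed once per
model on the pooled out-of-fold predictions (a per-fold-average mode
exists behind a flag; the pooled reading matches one-statistic-per-model
layout of the published validation table), and (ii) a 70/30 random
split. The combined ARV ranks the ten resulting statistics; every
candidate is refit on every training split, splits are unstratified and
seed-reproducible.

## Synthetic cohort generator

The study's 1,050-patient dataset is not deposited, so a calibrated
generator emulates its published structure. A standard-normal latent
health factor h drives both instruments:

* FACT domain d: `score = round(mean_d + 1.03·sd_d·(0.66·h + √(1−0.66²)·ε))`,
  clipped to [0, max_d]; the 1.03 inflation compensates discretisation
  shrinkage, and the loading 0.66 reproduces the target total-score SD
  given the per-domain targets (means 22.0/21.3/19.8/17.6/28.4, SDs
  3.6/3.5/2.8/4.5/6.6, total 109.2 ± 15.5).
* SF-6D dimension severity: `s_d = −(0.56·h + 0.34·q) + √(1−0.56²−0.34²)·ε`,
  cut at fixed thresholds into levels; q is an SF-6D-specific shared
  factor representing generic-instrument variance the FACT does not
  capture — without it, dimension noise averages out across the six
  dimensions and the total↔utility Spearman correlation cannot be held
  near 0.65 while the utility SD stays wide. Utilities follow by applying
  the tariff. Thresholds are stored as cumulative level shares, chosen
  once so the utility distribution lands near mean 0.690, SD ≈ 0.12,
  ceiling ≈ 0.3% and Spearman(total, utility) ≈ 0.65.
* Covariates: age ~ N(40.76, 11.33²) truncated to 19–78 and rounded; 76%
  female; TNM stage drawn with probabilities 93.7/5.4/0.5/0.4% but unused
  by any model, mirroring the study design.
* The all-worst (floor) state is excluded by construction: the rare
  joint-tail draw is bumped one physical-functioning level, so the floor
  count is exactly zero, as in the emulated sample, and the beta-mixture
  lower bound stays below every observation.

What the generator does **not** emulate: item-level response patterns,
the published per-dimension/per-item Spearman matrix (only the
total-level correlation is targeted), the exact skewness of the utility
distribution (the single-factor Gaussian construction yields a roughly
symmetric utility distribution; the real sample is skewed), and any
covariate dependence of age/gender on health. Passing tests therefore
demonstrate that the estimation and selection machinery is correct and
well-calibrated on data with the study's first- and second-moment
structure — not that the published coefficient values would be recovered
from real patients.

A second generator draws from the *exact* likelihood of any estimator
family (normal errors; censoring at 1; ordered-probit category draws;
beta-mixture draws with ceiling mass) for parameter-recovery tests,
which assert recovery within three standard errors at n = 5,000–10,000.

## Published coefficient crosswalk

The published coefficient tables (OLS and Tobit M1–M5, ordered-probit
M5 with its six cutpoint blocks, beta-mixture M5a) are transcribed at
printed precision, significance stars dropped. Suspected errata are kept
as printed and annotated: the Tobit M3 MAE of 0.7320 (probably 0.0732 —
but the printed ARVs are only reproduced with the printed value, so the
original ranking used it too), and the beta-mixture mass block whose
standard errors of order 10³–10⁶ mark separation; that entry is flagged
`unstable` and should not be relied on. The published full-sample and
validation metric tables are packaged as data so the rank arithmetic is
recomputable without any external source.

## Numerical and degenerate-input policy

Probabilities are clipped at 1e−300 before logs; beta-regression means at
1e−10. Rank-deficient designs error with the offending columns; all-censored
Tobit and single-category ordered-probit inputs error; a cohort entirely at
ceiling yields a flagged degenerate mass fit. Interior observations exactly
at a beta-mixture bound raise an error instructing bound adjustment rather
than silently shifting data. Fold assignment uses shuffled K-fold with the
given seed; identical seeds give bitwise-identical cohorts, splits and
reports.

## Problem sizes used in the shipped analyses

The analysis drivers and the acceptance script run the full pipeline at
the study's n = 1,050; distributional calibration checks use n = 5,000
and 50,000; recovery tests use n = 5,000–10,000; the beta-mixture
refits in the validation driver and acceptance script use 8 multi-starts
(the library default is 20), which on these well-separated synthetic
likelihoods reaches the same optimum.

## Known limitations

* The shipped tariff is synthetic; predictions from `oprobit:M5` with it
  are methodologically faithful but not Hong-Kong-valued utilities. Users
  with access to the real value set can supply it as a JSON tariff file.
* The response mapping assumes cross-dimension independence given the
  covariates when combining marginal level probabilities; the six
  dimensions of a real respondent are correlated beyond what covariates
  explain, which biases the expected-utility spread.
* The published betamix:M5a mass block is unusable in practice (see
  above); it is included for completeness only.
* No uncertainty is propagated into crosswalk predictions (no standard
  errors on mapped utilities), matching the published deliverable.
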