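# Methods

`prescvar` analyses how English general practices changed their prescribing
of a focal drug around a regulator-issued safety letter (a direct healthcare
professional communication, DHPC), using practice-level monthly dispensing
counts. The worked case is mirabegron (BNF `0704020AE`) within the
overactive-bladder drug class (BNF section `070402`) and the September 2015
EMA communication on hypertension risk. This note records the models, the
defaults and the design choices; nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Outcome and panel construction (`panel_io`)

The outcome for practice *p* in month *t* is the focal drug's percentage
share of its class,

    y_pt = 100 * focal_items_pt / class_items_pt,

aggregated from product-level rows by BNF-code prefix. The share is
undefined when the class denominator is zero; such practice-months are kept
in the panel but flagged, and dropped from model and variation rows rather
than imputed as zero — a 0/0 month carries no information about prescribing
propensity. Periods are `pandas` monthly `Period`s, so month arithmetic is
exact integer arithmetic.

Practice exclusions follow the conventions of studies built on NHS Digital
practice extracts: a practice is atypical if it has fewer than 750
registered patients, fewer than 500 or more than 5000 patients per
full-time-equivalent GP (strict inequalities; the boundary is retained), or
an undefined per-FTE ratio; and low-volume if any month from 13 months
before to 13 months after the communication (August 2014–October 2016 for a
September 2015 DHPC) has fewer than 100 prescription items. The volume rule
counts all items by default and can be switched to class items
(`items_col="class_items"`). The report lists each excluded practice once
with the first rule triggered, so retained + reported partitions the input.

## Segmented mixed model (`segmented_model`)

Time is coded with the anchor month (the month before the communication) at
`t = 0`; `post` switches on at `t = 2` (the month after the communication)
and `s = (t − 2)·post`. The communication month itself (`t = 1`) is a
transition month: prescriptions dispensed in it straddle the letter's
arrival, so it is excluded from fitting by default
(`include_transition=True` keeps it as a pre-period row; its coding places
it on the pre line either way).

The model is linear on the percentage scale:

    y_pt = (β0 + u0p) + (β1 + u1p)·t + (β2 + u2p)·post + (β3 + u3p)·s
           + Σ_m γ_m·month_m(t) + e_pt,
    (u0..u3)p ~ N(0, G) unstructured,   e_pt ~ AR(2)(ρ1, ρ2, σ²)

with eleven calendar-month dummies (January reference). β0 is the level at
the anchor month (% of class prescriptions), β1 the pre-communication trend
(%-points/month), β2 the immediate level change, β3 the change in trend.

Estimation is by numerical maximisation of the REML (default) or ML
criterion of the marginal model, in which each practice contributes
`V_p = Z_p G Z_p' + σ² R_p` with `R_p` the stationary AR(2) correlation at
the practice's observed (possibly gapped) months. Numerical choices:

- **Parametrisation.** G through its Cholesky factor with log diagonal
  (bounds ±[e⁻⁸, e⁶] on the SD scale); the AR pair through
  tanh-transformed partial autocorrelations, so every iterate is
  stationary; the innovation SD on the log scale. Fixed effects are
  profiled out exactly by GLS at each iterate.
- **Optimisation.** L-BFGS-B with numerical gradients, `ftol 1e-10`.
  Starting values split the pooled-OLS residual variance heuristically
  between the intercept/slope random effects and the noise.
- **Pattern caching.** Practices with identical observation-time patterns
  share one `V_p` Cholesky factorisation, so a balanced panel costs one
  n_t × n_t decomposition per likelihood evaluation regardless of the
  number of practices.
- **Degeneracies.** With no random effects and no AR terms the model is
  ordinary least squares and is solved in closed form. If the optimiser
  fails, a fall-back ladder drops the AR terms, then the slope-change
  random effect, recording each step; `strict=True` raises instead.
- **Wald inference.** 95% CIs are estimate ± 1.96·SE throughout.

Likelihood-ratio tests between nested random-effect structures use the
difference in variance-parameter counts as degrees of freedom against a
naive chi-square, which is conservative when a variance sits on the
boundary; the 50:50 chi-square mixture refinement is documented here but
not the default. LR comparisons should be run on ML fits (the function
warns on REML input).

Rows are unweighted — each practice-month counts equally — because the
model targets the practice-level percentage itself, not the pooled rate.
The known consequence is heteroscedasticity: the binomial noise variance of
a share with denominator ~λ is `100²·p(1−p)/λ`, which varies across
practices and over time. GLS with a misspecified weight remains unbiased
for the fixed effects; the practical effect visible in simulations is
inflation of the estimated level-change/slope-change variance components,
which the conditional BLUP standard errors absorb (classification stays
conservative, see below).

Counterfactual prediction zeroes the `post` and `s` contributions (fixed
effects and, at practice level, their BLUPs), extending the
pre-communication trend with seasonal effects as observed.

## Variation statistics (`variation`)

The systematic component of variation for one month, over practices with
observed focal counts `O_i` and expected counts
`E_i = class_i · (ΣO/Σclass)`, is the McPherson-style estimator on the
conventional ×100 scale:

    SCV = (100/k) Σ_i [ ((O_i − E_i)/E_i)² − 1/E_i ]

The `1/E_i` term removes Poisson sampling variation; a negative raw value
is truncated to zero (the raw value is retained in the output). Bands:
low < 3 ≤ moderate ≤ 5.4 < high ≤ 10 < very high. Each month the practice
set is first trimmed to shares within the month's 5th–95th percentiles
(inclusive bounds, linear-interpolation/type-7 quantiles, fixed for
reproducibility); trimming is on the share distribution, the natural scale
for "percentiles of prescribing".

The pre/post comparison takes the w = 6 months strictly before and after
the communication month (the month itself in neither window) and compares
median monthly SCVs with a two-sided Wilcoxon rank-sum test. For group
sizes ≤ 12 the null distribution is enumerated exactly over all
C(n1+n2, n1) rank splits with mid-rank ties; larger groups fall back to the
tie-corrected normal approximation.

Standardized prescribing ratios divide a practice's monthly share by the
pooled share across practices that month; the class-item-weighted mean
ratio is identically 1, which the tests assert as an algebraic invariant.
The rolling-ratio display divides each practice's trailing six-month mean
share by its share in a reference month (practices with zero or undefined
reference share excluded) and summarises months by deciles plus the 1st–9th
bottom and top percentiles.

## Responder classification and predictors (`practice_response`)

A practice is a *decrease* (resp. *increase*) responder on the level or
slope dimension when the 95% interval `BLUP ± 1.96·conditional SE` lies
entirely below (above) zero, and *no change* otherwise. Conditional
(posterior) SEs are the standard prediction-interval choice for BLUPs;
because BLUPs shrink toward zero, the null false-labelling rate is below
the nominal 5%. No multiplicity correction is applied across practices —
the classification is descriptive, and this caveat is deliberate.

Characteristics are modelled as predictors of decrease vs (no change ∪
increase) by multivariate logistic regression (`statsmodels` MLE), all
covariates entered jointly. Continuous covariates, including the IMD
decile, are z-scored over the practices entering the model so odds ratios
are per SD; the registrar indicator stays 0/1 (z-scoring a dummy harms
interpretability; `standardize_binary=True` overrides). Practices with
missing characteristics are dropped from this model only, and separation or
non-convergence is flagged in the result.

## Synthetic data (`synthetic_data`)

The generator is the generative mirror of the model above: latent
percentages from the segmented structure with MVN practice effects,
seasonal offsets summing to zero, and stationary AR(2) noise (initialised
from its stationary distribution); observed counts as
`class ~ Poisson(λ_p)` with per-practice lognormal volume λ (mean 76
items/month, log-SD 0.6, matching the scale and skew of practice OAB
volumes) and `focal ~ Binomial(class, clamp(μ,0,100)/100)`. Clamping is
counted and reported; under the default configuration it affects well under
1% of practice-months, concentrated in the earliest months where the
planted trend puts the latent mean near zero. Non-class items are drawn at
~40× the class volume so the low-volume exclusion rule has a realistic
total to act on. One seed drives five named sub-streams (profiles, effects,
volumes, noise, counts), so each stage is reproducible in isolation.

Defaults plant the published segmented-regression estimates as structural
truth (β = 8.30, 0.294, −0.023, −0.036) with random-effect SDs
(2.0, 0.05, 0.2, 0.02), corr(u0, u1) = 0.5 (practices that adopted early
also grow faster — and the positive correlation keeps early-period latent
shares away from the zero clamp), ρ = (0.3, 0.1), σ_w = 1.0. Named
configurations:

- `recovery_config` — seasonal and AR terms zero; the conditions of the
  parameter-recovery study.
- `null_predictor_config` — slope-change SD widened to 0.5 so both
  responder classes are populated at modest panel sizes, deltas zero; the
  conditions of the predictor null-control study.
- `paper_like_config` — full scale (7408 practices) with intercept SD 4.0.
  A Gaussian intercept spread matching the real cross-sectional SD (~6.8)
  around an early-period mean of ~2.7% would clamp a large share of latent
  values at zero, so the generator deliberately under-disperses the
  cross-section; the linear-Gaussian mirror cannot reproduce the skewed
  real distribution without breaking the model it exists to test.

Covariate distributions (lognormal list size with GP FTEs scaling as list
size over a lognormal patients-per-FTE ratio, normal percentage mixes,
~25% registrar practices, uniform IMD deciles) are moment-matched to
published descriptives of English practices; the FTE–list coupling keeps
the per-FTE exclusion rules from firing on a large fraction of synthetic
practices, mirroring the few-percent exclusion rate of the real extracts. The
`delta_level` / `delta_slope` vectors shift a practice's level/slope
deviation by a linear combination of its standardized characteristics (in
%-point units per covariate SD), planting associations for the predictor
model; with both zero, response is independent of characteristics.

What the generator does **not** emulate: the zero-inflated, right-skewed
share distribution of real practices (Gaussian effects + clamping instead),
practice openings/closures and list churn (balanced panels), spatial
correlation, and denominator drift over time (λ_p is constant within
practice). Passing tests therefore demonstrate correctness of the
estimators under the assumed data-generating process, not robustness to
these real-data features.

## Validation studies and problem sizes

- **Parameter recovery** (`studies.recovery_study`, also the acceptance
  script): 10 replicates × 500 practices × 39 months under
  `recovery_config`, fitted with all four random effects and `ar_order=0`
  (matching the generating conditions); replicate means of the four
  structural estimates are compared with the planted values. At this
  problem size the replicate-level sampling SD of the level-change
  estimate is ~0.15 %-points (consistent with its published standard
  error scaled from 7408 to 500 practices), so its 10-replicate mean
  carries a Monte-Carlo SE near 0.05 — the widest-variance quantity the
  study tracks.
- **Null classification control**: one 500-practice run with
  β2 = β3 = 0 and zero change-effect SDs; the fraction of practices
  labelled increase or decrease must stay ≤ 10%.
- **Null predictor control** (`studies.null_predictor_study`): 100
  replicates × 150 practices under `null_predictor_config`; ≥ 90% of
  covariate OR CIs must cover 1. Sizes were chosen so the full
  pipeline — fit, classification, logistic model — runs in every
  replicate with a well-populated responder class.
- **Oracle equivalences**: the SCV against an independently coded loop
  evaluation; the exact rank-sum p against full enumeration and SciPy's
  exact method on tie-free data; the no-random-effects/no-AR fit against
  closed-form least squares; the REML objective against
  `statsmodels.MixedLM` evaluated at the same parameters.

Replicate seeds derive from a single master seed through a
`numpy.random.SeedSequence`, and every generator consumes only streams
spawned from it.

## Known limitations

- The AR(2) applies to the total within-practice error, which in truth
  mixes an autocorrelated latent process with white binomial sampling
  noise; fitted AR coefficients are attenuated accordingly.
- Variance components for the change effects absorb unmodelled
  heteroscedasticity and should be read as descriptive, not structural;
  classification relies on conditional SEs, which remain conservative.
- The LR test's naive chi-square reference is conservative for boundary
  variance tests.
- Standard errors ignore uncertainty in G, ρ and σ² (the usual empirical-
  BLUP caveat).
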