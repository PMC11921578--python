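# Methods

This note records the generative model behind the synthetic cohorts, the
statistical procedures, the numerical choices, and the limits of what the
package's passing tests establish.

## The measurement model

A chimeric faces task presents, on every trial, two mirrored versions of the
same half-emotional/half-neutral face and asks which looks more emotive.
Because the left visual field projects first to the right hemisphere,
habitually choosing the face whose emotive hemiface sits in the left visual
field indexes right-hemisphere dominance for facial emotion processing. Two
per-participant indices summarise a session:

* **LQ1** = (N_L − N_R) / N_total — choice bias. N_total counts the
  participant's *valid responded* trials after cleaning (the nominal-192
  denominator is available behind `PipelineConfig.lq1_denominator =
  "nominal"` for auditing; with few removed trials the two differ little).
* **LQ2** = (RT_R − RT_L) / RT_Total — reaction-time bias, from arithmetic
  means of raw milliseconds. Slower right-visual-field-emotion choices give
  positive LQ2, matching LQ1's sign convention. LQ2 is undefined for a
  participant who never chose one side; such participants enter the LQ1
  model but not the LQ2 model.

## The synthetic cohort generator

The generator's defaults describe one fixed study condition: an online adult
general-population cohort of 427 (sex split 214/210/3
female/male/undisclosed), performing 192 task trials (happy/angry/fearful,
64 each, top/bottom placement counterbalanced within emotion) inside a
4.5 s response window. Components, with the reasoning behind each:

* **Age** — truncated normal on [18, 67]. `age_mean`/`age_sd` are the
  *target cohort moments* (defaults 27.23 / 8.43 years); the generator
  numerically solves for the truncated-normal location/scale that realises
  them, because a crowdsourced adult cohort is strongly right-skewed and a
  naive truncation of N(27.23, 8.43²) would land at mean ≈ 29.8, sd ≈ 7.3.
  `age_sd = 0` degenerates to a point mass.
* **Handedness** — a latent EHI score from a three-component *censored*
  normal mixture on [−100, 100]: right (weight 378/427, N(128, 32²)),
  ambidextrous (10/427, N(10, 30²)), left (39/427, N(−100, 38²)). Censoring
  (clipping, not resampling) piles mass at ±100 exactly as real EHI data do
  — many respondents tick "strong right" on all ten items. The latent is
  then mapped to ten valid 5-level item responses: each item is a weak
  (one-check) item with probability 0.25, otherwise a two-check item, with
  checks falling right with probability (latent+100)/200; the scored
  instrument is unbiased for the latent. Scored moments land at ≈ 77.8 /
  55.3, and the mixture component doubles as the self-reported handedness
  category (right/left/ambidextrous ≈ 89/9/2%).
* **Autistic traits** — a Gaussian copula correlates five latent subscale
  scores (defaults: social skills 22.84 ± 5.07, attention switching
  25.20 ± 4.26, attention to detail 25.24 ± 5.05, communication
  20.88 ± 4.90, imagination 20.12 ± 3.89; correlations 0.30 among the
  socially loaded subscales, 0.10 with attention to detail). Each rounded
  target score (clipped to 10–40) is spread uniformly at random over the
  subscale's ten items via a multivariate hypergeometric draw with per-item
  cap 3, then keyed values are converted to raw 1–4 responses through the
  instrument key. Item *sums* therefore match the target moments; item-level
  responses make no claim to psychometric realism (a deliberate non-goal),
  so the Cronbach-α values the pipeline reports on synthetic data
  (≈ 0.5–0.75) emerge from the copula, not from item modelling.
* **Task behaviour** — two latent traits per participant, each a linear
  function of covariates (`effect_map`, raw scale, `a:b` keys for products)
  plus Gaussian noise:
  * *choice bias* b: P(choose left-VF-emotion face) = logistic(b). Any
    monotone link would do since the analysis only sees LQ1; logistic gives
    the closed form E[LQ1] = 2·logistic(b) − 1 used throughout the tests.
    Default b = 0.22 + 0.002·EHI + N(0, 0.72²), putting LQ1 at ≈ 0.17 ± 0.32
    with a small positive handedness effect.
  * *RT bias* δ: reaction times are lognormal (base 1000 ms, σ_log = 0.4)
    with the log-location shifted by ±δ/2 according to the chosen side —
    positive support, heavy right tail, and E[LQ2] ≈ δ for small δ. Default
    δ = −0.0808 + 0.004·attention-switching − 0.141·male +
    0.007·imagination·male + N(0, 0.06²), so LQ2 sits at ≈ 0.02 ± 0.09 with
    an attention-switching main effect and an imagination-by-sex interaction
    (the −0.141·male term recentres the interaction so the sexes stay
    comparable on average). RTs above the 4.5 s window become non-response
    trials (no choice, no RT).
* **Attention checks** — 2–4 in-task check trials (uniform draw; the exact
  count per session is not pinned down by the protocol, so the uniform draw
  is a package choice), plus a post-task instruction question and one AQ
  check, for ≥ 4 total; pilot-protocol participants get 4 in-task (6 total).
* **Determinism** — all randomness fans out from the single config seed via
  `numpy` SeedSequence spawn keys, one stream per participant, so subsetting
  a cohort never changes anyone else's data, and identical configs produce
  byte-identical CSV bundles.
* **Contaminants** — `inject_contaminants` marks disjoint participant sets:
  bots (invalid free-text check), inattentive responders (exactly
  threshold-many failed checks: 2 standard / 3 pilot, plus one
  near-threshold passer for boundary coverage), fast-guessers (11 trials
  pushed under 200 ms) and non-responders (11 trials blanked). Eleven bad
  trials leave 181/192 = 94.3% valid, just under the 95% gate. Ground truth
  stays in `truth_*` columns that the analysis never reads.

## Cleaning

Rules run in a fixed, logged order: completeness → attention gate → bot
gate → response-pattern flag → fast-trial filter → completion gate.
Decisions worth stating:

* The 200 ms filter is strict ("below"): 199 ms is removed, 200 ms kept.
* The completion denominator is the 192 task trials — attention checks and
  practice are outside it — and non-response (timeout) trials count as
  invalid, since completion is about produced responses.
* The response-pattern flag is a deterministic stand-in for a human
  eyeballing response logs: it trips on a run of more than 25 identical
  response keys (top/bottom, reconstructed from chosen side × layout) or a
  binary key entropy under 0.10 bits. Both thresholds are config-exposed
  because no published criterion exists; they are deliberately permissive so
  genuine responders are essentially never flagged.
* The bot check arrives as a precomputed boolean; free-text adjudication is
  out of scope.
* Undisclosed-sex participants survive cleaning and appear in sex-free
  descriptives but are removed from any model involving sex.

## Regression models

Both models regress a quotient on 13 raw (uncentred, unstandardised) terms:
EHI score, age, male indicator (female reference), five AQ subscales, and
the five subscale-by-male products. With n complete cases the residual df is
n − 14. Per term the table carries the estimate, SE, t, two-sided p, t-based
95% CI (so p < 0.05 exactly when the CI excludes 0), and
sr² = t²(1 − R²)/df_resid, which equals the R² drop from refitting without
the term (asserted to 1e−10). Diagnostics: Durbin–Watson, Breusch–Pagan in
the studentised Koenker form (robust to non-normal errors), Shapiro–Wilk.
No multiple-testing correction is applied across coefficients, and no
robust/HC standard errors are offered — the frequentist table is the plain
OLS one. Rank-deficient designs fail with the collinear columns named.

## Bayesian model averaging

The model space is fixed by design at 10 models: intercept-only, eight
single-main-effect models, and the full 13-term model; interactions appear
only in the full model. With uniform prior probabilities 1/10 this gives
prior inclusion 0.20 per main effect and 0.10 per interaction. Evidence per
model is the BIC approximation to the Bayes factor against the null,
BF = exp((BIC₀ − BICₘ)/2), with the Gaussian profile likelihood
ln L̂ = −(n/2)(ln 2π + ln(RSS/n) + 1) and k counting intercept, slopes and
the variance parameter (any constant-offset convention for k cancels in the
differences; this one is frozen and tested). BF_Inclusion compares
posterior to prior inclusion odds marginalised over the *whole* space
("all-models" comparison, not matched pairs). All of it runs in the log
domain: a full model 1400 BIC points behind the null still yields finite
log inclusion BFs (magnitudes like 1/10¹²), and reciprocal reporting (1/BF)
is available for evidence against inclusion. Labels follow the conventional
bands — weak 1–3, moderate 3–20, strong 20–150, very strong > 150 — with
upper edges inclusive, applied to BF or its reciprocal with a direction tag.
This is deliberately *not* the mixture-of-g-prior Bayes factor some R
packages default to; numerical equality with those is not claimed.

## Problem sizes and seeds in the test suite

The replicate studies in the acceptance suite use 200 cohorts of 427 for
parameter recovery (sign agreement and CI coverage of the handedness
coefficient, with the population projection slope obtained from a 200 000-
participant expected-LQ1 regression) and 1000 cohorts of 424 for null
calibration (per-coefficient type-I error). The null study draws LQ1 from
its exact binomial trial marginal rather than expanding 192-row logs per
replicate — a shortcut the suite itself validates against the full
generator. All replicate seeds are fixed offsets from module constants.

## What passing tests do and do not show

The simulator matches the marginal moments and the coarse dependence
structure the analysis assumes — it does not emulate real response
processes: no stimulus-level variation (every trial is exchangeable given
the traits), no learning, fatigue or drift over the session, no
emotion-specific bias, no item-level AQ structure, and contaminants are
stylised. Green tests therefore certify that the *pipeline* is correct
(scoring, cleaning, indices, models, model averaging, bookkeeping) and that
it recovers effects the generator plants at realistic sizes; they say
nothing about whether those effects exist in real cohorts. Real data enters
through the same two CSV schemas (`participants.csv`, `trials.csv`) and
flows through the identical code path.

## Known limitations

* LQ2's generative link (location shift on log-RT) is one of many
  reasonable choices; only its sign convention and approximate magnitude
  are constrained by the analysis.
* The pattern flag cannot reproduce an unrecorded manual review; it is a
  documented, configurable proxy.
* `model_bic` requires RSS > 0 and so refuses saturated/perfect fits.
* Cronbach's α requires ≥ 2 items, ≥ 3 rows and nonzero total variance;
  degenerate inputs raise rather than return a value.
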