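# Methods

## The measurement model

The package scores two linked instruments.

**TFEQ-R18.** Eighteen items load on three subscales: cognitive restraint
(CR, 6 items), uncontrolled eating (UE, 9 items) and emotional eating (EE,
3 items). Each subscale's raw sum is rescaled as
`(raw − min_possible) / (max_possible − min_possible) × 100`, which is exact
at the anchors (all-minimum → 0, all-maximum → 100) for any per-item
response range, so the item ranges are configuration rather than hard-coded.
The default map uses the standard published assignment
(CR: 2, 11, 12, 15, 16, 18; UE: 1, 4, 5, 7, 8, 9, 13, 14, 17; EE: 3, 6, 10)
with every item on a 1–4 scale; reverse-keyed items are flipped within their
range before summation. UE and EE are typically strongly correlated
(r ≈ 0.7), so a *disinhibited eating* composite is formed as their
arithmetic mean and used as the second predictor alongside CR. Missing items
are an error by default; an optional prorating mode substitutes the mean
response fraction of the answered items in the subscale. Cronbach's alpha
uses unbiased (n−1) variance estimators.

**Dietary decision-making task.** The referent food is the rated item
minimizing Euclidean distance to the participant's (median taste, median
health) point; ties go to the lowest item id, and a Chebyshev metric is
available since "closest to the median on both" does not pin the metric
down. Per-trial difference scores are defined only on trials with a
non-neutral preference: the preferred food's rating minus the non-preferred
food's rating, separately for health and taste (each necessarily in −4..4
for 1–5 ratings), and their composite health-minus-taste score in −8..8,
collapsed to ±5 because the extreme cells are rare and poorly estimated.
The collapsing map is idempotent and order-preserving, and all derived
scores are invariant under swapping target/referent while negating the
preference.

Per-participant sensitivities come from OLS of preference (−2..+2) on an
intercept plus the target-minus-referent health and taste differences over
all completed trials. Neutral (preference 0) trials are included: 0 is a
valid value on the preference scale, and only the *difference scores* are
restricted to preferred trials. Rank-deficient designs (e.g. constant
raters) yield NaN sensitivities and a logged count rather than an error.

RT trimming removes trials outside mean ± 2.2 SD, computed in a single pass
(not iterated) within the trimming unit — per participant by default, with
a pooled option, since the trimming unit is a genuinely open choice and
per-participant is the RT-literature default. Zero-variance units remove
nothing. Under normality the rule removes 2·Φ(−2.2) ≈ 2.78 % of trials.

## Inference

Cleaning excludes implausible heights (< 0.6096 m, i.e. 2 feet), BMI below
a configurable floor of 10 kg/m² (a generic plausibility bound rather than
an ad hoc case deletion), and invariant responders — the same preference on
every trial together with constant taste and health ratings. Weight status
uses CDC cut points (BMI < 25 healthy, 25–29.9 overweight, ≥ 30 obese).

Covariate screening computes pairwise Pearson correlations between each
demographic variable and every outcome; categoricals enter as indicator
columns against the most frequent level. A variable whose *any* correlation
has p < 0.10 becomes a covariate. Outcome models z-score all continuous
variables, so unadjusted simple slopes equal Pearson correlations — an
identity the tests exploit. RT models are pooled trial-level OLS with RT in
ms; difference scores stay in raw rating units so coefficients read as ms
per unit, while trait predictors are z-scored. Cluster-robust (by
participant) standard errors are available behind a flag but off by default,
matching the pooled-OLS analysis form the pipeline mirrors.

Moderation uses the median split with ties assigned to the low stratum
(deterministic), per-stratum covariate-adjusted slopes, and a pooled
difference × group interaction tested by Wald t at p < 0.10; the
continuous form replaces the group indicator with the z-scored moderator.
When the moderator is binary the two forms test the same linear hypothesis
and give identical p-values, which the tests verify as a degenerate-
distribution check.

## The synthetic cohort

The generator emulates the data structure the analysis assumes, with every
latent written to a ground-truth table the scoring pipeline never reads.

*Traits.* (CR, UE, EE) are drawn from a clipped multivariate normal on the
0–100 scale with defaults CR ≈ 42 ± 22, UE ≈ 36 ± 19, EE ≈ 36 ± 28,
matching typical adult samples. The configured UE–EE correlation
(default 0.70) is the target for the *scored* subscales; because clipping
to [0, 100] and item discretization attenuate correlations, the latent
normal correlation is inflated by a fixed factor of 1.12, calibrated once
at the defaults. TFEQ items discretize each trait onto the 1–4 item scale
with Gaussian item noise (SD 0.3), so scored subscales recover the traits
with r > 0.9.

*Foods and ratings.* Each food has a latent (taste, health) pair from a
bivariate normal (mean 3, SD 1) with correlation −0.3 — tasty foods tend to
be rated less healthy. Participant ratings add noise (SD 0.6), round, and
clip to 1..5.

*Preferences.* Trial utility is
`u = w_health·Δhealth + w_taste·Δtaste + ε`, mapped to −2..+2 by fixed
symmetric thresholds (±0.5, ±1.5 utility units); the task itself never
models preference generation, so any monotone map would do and a fixed one
keeps noiseless limits exact. Weights are
`w_health = 0.35 + 0.05·z(CR) − 0.025·z(DE) + N(0, 0.18)` and conversely
for `w_taste` (base 0.65): restraint raises the health weight,
disinhibition the taste weight. The gammas are set so standardized
trait→outcome coefficients land around 0.2–0.3 — the same order as
published eating-behavior effects — while the trait-independent weight
spread (SD 0.18) dominates between-person variance; that matters because
per-participant slope heterogeneity correlated with the trial-difference
distribution would otherwise bias the pooled RT models. Utility noise
(SD 0.4) is small enough that 49 trials recover the weights with r > 0.9.

*Reaction times.* `RT = base_i − b_health·hd − b_taste·td`, multiplied by
lognormal noise (σ = 0.15) and clipped to [200 ms, 4000 ms] (stimulus cap);
`hd`/`td` are preferred-minus-non-preferred differences (0 on neutral
trials). Defaults put the mean near 1.3 s with slopes −13 and −11 ms per
unit. The slopes are trait-modulated: `b_health = 13 + 8·(z_CR − z_DE)` ms
and `b_taste = 11 − 8·(z_CR − z_DE)` ms, giving median-split stratum
contrasts of roughly 7–15 ms that the pooled interaction test detects
reliably at n = 500. A configurable fraction of trials (2 %) receives
2–3× inflated RTs to exercise the trimming stage, and participant-level
intercepts (SD 40 ms) plus an age slope (5 ms/year) give covariate
screening real signal to find.

No drift-diffusion or sequential-sampling process is modelled: the
generator only needs to produce the linear difference-score slopes the
analysis estimates.

## What the simulation does and does not show

Passing tests on synthetic cohorts demonstrate that the scoring recovers
known parameters and that the inference chain has the advertised
operating characteristics (nominal interaction size ≈ 0.10 under the null,
sign patterns under trait-linked generation). They do not show that real
participants behave like the generator: real RT data have much larger
between-participant variance than the 40 ms intercept SD used here — kept
small deliberately, because the pooled-OLS Wald tests the pipeline mirrors
assume independent errors and large participant-level variance components
inflate their size (on real data the cluster-robust flag is the safer
choice). Real ratings also have idiosyncratic item effects, response styles
and hunger-state dependence that the generator omits.

## Numerical choices

- OLS goes through statsmodels; tests cross-check every fitted path against
  an independent normal-equations solver at 1e-8.
- Referent ties: lowest item id. Median split ties: low stratum. Utility
  exactly on a threshold maps to the higher category (measure-zero under
  any noise).
- Zero total-score variance makes Cronbach's alpha NaN with a warning;
  zero RT variance trims nothing; constant screening variables are skipped
  with a warning; empty strata and empty post-cleaning cohorts are hard
  errors.
- Generator determinism is bit-exact for identical (config, seed); one
  `numpy` Generator seeds every stage.

## Problem sizes

Default simulated studies use 500 participants × 50 foods × 49 trials —
the scale at which the moderation analyses have stable power. The null
calibration check uses 200 replicates of 150-participant cohorts, a size
chosen to keep the full suite fast while leaving Monte-Carlo error on the
flag rate near ±0.02.

## Known limitations

- The trial-level models ignore within-participant RT correlation by
  default (fidelity to the pooled analysis form); use `cluster_robust=True`
  for honest standard errors on clustered data.
- Single-predictor trial-level RT slopes inherit omitted-variable bias
  whenever health and taste differences correlate; the joint
  (simultaneous) model is the stable summary and the one the acceptance
  script reports.
- The deposited-data schema is supported through `analyze` mode, but no
  external dataset ships with the package; all validation is synthetic.
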