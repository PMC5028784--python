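# Methods

`actipain` implements the quantitative pipeline of a cross-sectional
chronic-pain cohort study in people living with HIV: questionnaire scoring
with truncated-translation renormalisation, polychoric factor-analytic
validation of ordinal resilience scales, actigraphy phenotype extraction
with an inactivity threshold and endurance bins, resampling-annotated
univariate inference, and random-forest variable importance with an
informativeness threshold.  A seeded synthetic-cohort generator with known
ground truth makes every stage testable end to end.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Questionnaire scoring

The Resilience Scale (RS) is 25 items scored 1–7 (totals 25–175); the
CD-RISC is 25 items scored 0–4 (totals 0–100).  Translated isiZulu forms
retain 23 and 24 items respectively after psychometric curtailment, so
their totals are rescaled by the exact ratio `n_full / n_retained`
(25/23 ≈ 1.09, 25/24 ≈ 1.04).  We apply the exact rational factor rather
than the two-decimal presentation: the rounded factors are display values,
and only the exact ratio maps the truncated scale's extremes onto the full
scale's extremes.  The Brief Pain Inventory interference score is the
arithmetic mean of its seven items; the "average pain" intensity item is
absent by design.  No missing-item imputation is performed anywhere — a
missing item is an error.  Chronic pain is classified as pain on most days
of the week for at least the past three months; shorter (acute) episodes
classify as no-chronic-pain.

## Actigraphy phenotypes

Counts from each accelerometer are first expressed as a percentage of that
device's calibration maximum, making devices with different sensitivities
comparable; the entire downstream pipeline is invariant to a joint
rescaling of counts and maximum.  Counts above the maximum (calibration
drift) are clamped to 100 % with a warning rather than allowed to create
impossible intensities.

Analysis uses the last 7 complete days of a (nominally 14-day) wear.  A
*complete day* is a midnight-to-midnight calendar day with all 1440 epochs
present and flagged worn; days broken by non-wear are skipped, and a
participant with fewer than 7 complete days raises an error (mirroring the
exclusion of inconsistent wearers).  Day boundaries at local midnight are a
package choice: the source protocol sums "over 24 h" without defining day
starts.

* **Time active** — successive non-overlapping 5-minute windows aligned to
  midnight; a window is *inactive* when its mean is below 2.5 % of the
  device maximum (strictly: a mean of exactly 2.5 % is active).  Active
  windows × 5 min are summed per day and averaged over the 7 days.
* **Intensity** — the median of 1-minute normalized epochs inside active
  windows, pooled over the week.  "Median daily activity for the week" can
  also be read as the median of 7 daily medians; both readings are
  implemented (`ActivityConfig.intensity_method`), pooled is the default.
* **Endurance** — minutes at 0, 1–24, 25–49, 50–74 and ≥ 75 % of the
  participant's own maximum 1-minute epoch in the analysed week, computed
  at epoch (not window) resolution since "maximum recorded activity" most
  naturally means the recording resolution.  Zero counts are their own
  category, so the five bins always partition exactly `7 × 1440` minutes.

## Scale validation

Resilience items are ordered categories, so all structure analysis runs on
the **polychoric** correlation matrix: for each item pair, thresholds are
set from the marginal cumulative proportions via the inverse normal
(two-step estimator) and the latent correlation maximises the
bivariate-normal contingency-table likelihood, clamped to ±0.999.  The
bivariate normal CDF is evaluated with a 48-node Gauss–Legendre quadrature
of the single-integral representation; it matches reference values to
~1e−10 over the usable range.  Empty response categories are collapsed
before threshold estimation so all thresholds stay finite.  Matrices that
fail positive definiteness (common at small n) are repaired by eigenvalue
clipping at 1e−6.

**Factor retention** uses Horn's parallel analysis: the observed polychoric
eigenvalues are compared, position by position and stopping at the first
failure, against criterion eigenvalues from simulated datasets of
independent items resampled from the observed margins (default 200
datasets; criterion = mean, with a 95th-percentile option).  For the
criterion datasets a first-order *linearised* polychoric estimator is used
— the Pearson correlation of the categorised data divided by per-item
attenuation factors `Σφ(τ)/sd` — because under independence it matches the
ML estimator's null sampling distribution to first order at a small
fraction of the cost.  With the mean criterion and pure-noise data, the
observed leading eigenvalue exceeds the mean of its own null distribution
roughly half the time, so a zero-factor decision is only reliable under
the 95th-percentile criterion; factor counts of one or more are recovered
essentially always in the simulated regimes we test (loadings ≥ 0.7,
n = 500, 10 items).

**Extraction** is minimum-residual (least-squares) factoring: uniquenesses
are optimised by L-BFGS-B (bounded to [0.005, 1], initialised at
1 − squared multiple correlation), loadings from the leading eigenpairs of
the reduced matrix.  Solutions with ≥ 2 factors are rotated by **direct
oblimin** (γ = 0) via the gradient-projection algorithm; the rotation is a
change of basis, so Λ Φ Λᵀ is preserved to numerical precision.  The
rotation starts from a fixed slightly-oblique basis because perfectly
symmetric loading patterns make the identity a (non-minimal) stationary
point of the criterion.

**Pruning** removes items one at a time — the single item with the
smallest maximum absolute loading below the 0.3 cutoff — then refits,
until every retained item loads at ≥ 0.3; removal order is recorded and
pruning below three items is an error.  One-at-a-time removal is the
natural reading of "removed successively".  Internal consistency reports
raw Cronbach alpha (integer scores) and ordinal alpha (standardised alpha
of the polychoric matrix).

## Resampling inference

Each univariate comparison carries a classical p-value plus a 95 %
percentile bootstrap CI (default 10,000 stratified resamples — groups are
resampled separately) and a permutation p-value (default 10,000 label
permutations).  The permutation p uses the add-one estimator
`(1 + #{|stat*| ≥ |stat|}) / (P + 1)`, which cannot be zero; when the
number of distinct assignments is at most 20,000 the permutation
distribution is enumerated exhaustively instead.  The bootstrap CI is the
percentile interval (not BCa): the simplest reproducible choice given no
stated variant.  The t-test is pooled-variance by default (a Welch option
exists), the rank-sum test uses exact enumeration for ≤ 20 observations
without ties and a tie-corrected normal approximation otherwise, Fisher's
exact test uses the probability-mass two-sided rule, and the trend test is
Cochran–Armitage with equally spaced scores 0..k−1 (the statistic is
invariant to positive affine score transforms).

## Forest importance, moderation, beta regression

The activity-prediction stage grows regression forests of CART trees on
bootstrap samples with `mtry = 3` candidate predictors per split and
minimum leaf size 5 (conventional defaults where unstated).  Importance is
the mean out-of-bag increase in squared error after permuting a predictor.
When correlation between predictors is assumed (`correlation_aware`, the
default), the permutation runs within quartile strata of the predictor's
most-correlated covariate (|Spearman r| > 0.2) — a desk-scale
approximation of conditional importance that preserves the dependence the
permutation would otherwise destroy.  A predictor is *informative* when
its importance exceeds the absolute value of the most negative importance
(threshold 0 when none is negative, in which case every positive-importance
predictor is informative); the model is refit four times with different
tree counts and seeds (exposed defaults 250/500/750/1000 trees) and only
predictors informative in all four runs are *consistently informative*.
Because all four runs share the data, chance predictor–outcome
correlations survive the intersection in a minority of null datasets; the
protocol suppresses most, but not all, false positives.

Moderation is OLS on centred predictor and moderator with their product;
simple slopes are evaluated at moderator mean and mean ± 1 SD with SEs from
the coefficient covariance.  Quality-of-life (VAS/100) models use beta
regression (statsmodels `BetaModel`) with a logit mean link and constant
precision φ; boundary values are compressed by `(y(n−1)+0.5)/n`, and
pseudo-R² is the squared correlation of linked fitted values with the
linked response.

## Synthetic-data generator

The generator's defaults encode the emulated study conditions: n = 197
with half the cohort in chronic pain, ~77 % isiZulu-language completers,
a latent resilience deficit of 0.7 SD in the pain group (the standardised
full-cohort difference implied by the published group means), a worry
log-odds shift of 1.4, and a *null* activity difference.  Questionnaire
items follow a one-factor graded-response model — `category =
#{thresholds below λθ + N(0,1)}` with default loadings 0.7 and thresholds
chosen to reproduce the high published score levels — matching the
unidimensional structure the factor validation assumes.  Worry items come
from a proportional-odds model whose baseline cutpoints reproduce the
published no-pain marginal frequencies.

Activity traces are built at 5-minute window resolution: an 8-hour sleep
block with per-night Gaussian jitter (SD 30 min) on a 22:00 onset, and,
while awake, a two-state process with geometric bout durations (mean
active bout 10 min) initialised at stationarity, so expected extracted
active minutes equal the configured truth exactly.  Active windows draw
gamma(3) epoch counts with mean 25 % of the device maximum — right-skewed,
with 99.9th percentile ≈ the maximum, so normalized counts essentially
never exceed 100 % — and inactive wake windows contain occasional small
"fidget" counts guaranteed below the 2.5 % threshold.  Device maxima are
drawn uniformly on 800–1200 counts/min to exercise the calibration
invariance.  Mean daily active minutes default to 360 ± 80 (an average of
~18 h/day inactive, as in the emulated cohort).

What the generator does **not** emulate: the real joint demographic
distribution, device noise and non-wear behaviour beyond explicit injected
episodes, weekday/weekend structure, item-level translation effects, or
any dependence of activity on pain (unless configured).  Passing tests
therefore demonstrate the correctness and calibration of the *methods*
under a controlled data-generating process, not claims about real
participants.

## Problem sizes and numerical choices

Simulation-based tests use scaled problem sizes chosen as a compromise
between Monte-Carlo error and runtime: 2,000 null datasets (n = 30/group)
for type-I calibration; 100 simulations each for one- and two-factor
parallel-analysis recovery (n = 500, 100 comparison datasets); n = 20,000
for polychoric recovery of ρ = 0.5 at tertile cuts; 100 seeds for the
planted-signal forest check with stability runs of 50/100/150/200 trees;
200 replicate traces for the generator/extractor round trip.  Tolerances
follow the statistic's own sampling error (typically 3 SE).  Optimiser
settings: polychoric Brent tolerance 1e−5 on ρ; minres L-BFGS-B ftol
1e−12; oblimin gradient-projection tolerance 1e−6, max 1000 iterations.
Ties and degenerate inputs: all-zero traces yield a flagged missing
intensity and a full zero endurance bin; constant outcomes, single-category
items, collinear designs and zero-variance comparisons raise errors rather
than returning numbers.

## Known limitations

* The linearised polychoric criterion in parallel analysis is exact only
  near zero correlation; it is not used for observed data.
* Conditional (correlation-aware) importance is a stratified-permutation
  approximation, not a conditional-inference forest.
* Ordinal alpha uses the standardised (mean-correlation) form rather than
  a factor-model reliability coefficient.
* The permutation and bootstrap engines treat the two-group design only;
  k-group designs are out of scope.
* EQ5D index (tariff) values are not computed — domain levels and VAS are
  carried as-is.
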