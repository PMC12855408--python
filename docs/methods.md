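# Methods

## Overview

`triboostcardio` implements a cardiovascular-disease (CVD) detection
pipeline for tabular clinical records and wearable vital-sign streams:

1. **Synthetic cohorts** with known ground truth stand in for the public
   CVD tabular datasets the pipeline targets.
2. **Preprocessing**: scalar Kalman smoothing of vital-sign streams,
   duplicate removal, mean/median imputation, an age-aware heart-rate
   anomaly flag, and min-max normalization fit on training data only.
3. **Feature selection**: a refracted sand-cat swarm optimizer (RL-SCSO)
   wrapped around a cross-validated classifier error.
4. **Classification**: a majority-vote ensemble of three boosters —
   a CatBoost-style symmetric-tree gradient booster, AdaBoost, and
   LogitBoost — evaluated with a ten-metric diagnostic suite.

## Synthetic cohort generator

Each of the `n_informative + n_noise` features has an independent
standard-normal latent `z_j`. The binary target is drawn from a logistic
model on the informative latents only,

    P(y=1 | z) = sigmoid(b + sum_j beta_j z_j),

with user-supplied log-odds effect sizes `beta` and the intercept `b`
solved numerically (Brent root-finding) so the expected positive rate
equals `class_balance`. Noise columns never enter the model, so they are
exactly independent of the target.

Observed columns follow the clinical schema the pipeline targets —
age, sex, chest-pain type, resting blood pressure (94–200 mmHg), serum
cholesterol (126–564 mg/dL), fasting blood sugar, resting ECG, maximum
heart rate (71–202 bpm), exercise-induced angina, ST depression
(oldpeak, 0–6.2), ST slope, and vessel count — with target coding
0 = absence, 1 = presence of disease. Numeric attributes are min-max
mapped from their latent onto the declared bounds (monotone in the
latent, so effects survive the mapping and declared ranges hold exactly);
categorical attributes are quantile-coded into equally probable integer
levels. Defaults (`n=2000`, 4 informative + 16 noise features, effect
size 2, balanced classes) define the study conditions used throughout the
tests and the acceptance script.

What the generator does **not** emulate: the joint correlation structure
of real clinical cohorts (features are conditionally independent), label
noise beyond the logistic link, covariate shift, and measurement units
interacting (e.g. age-dependent cholesterol). Passing tests therefore
demonstrate method correctness and recovery of planted signal, not
clinical performance on real data.

Vital-sign streams are `baseline + N(0, noise_sd) + spike·1[artifact]`
with entries masked missing at `missing_rate` — the dropout/motion
artifact failure modes of wearable monitors. Defaults: 1 Hz cadence,
baseline 75 bpm, noise SD 3 bpm, 1% artifacts of +40 bpm, 2% missing.

## Scalar Kalman filter

The filter names a random-walk state model — identity transition with
process noise `q` and measurement noise `r` — the simplest model
consistent with smoothing a slowly varying vital sign:

    predict:  P <- P + q
    correct:  K = P/(P+r);  x <- x + K(z - x);  P <- (1-K)P

Missing samples receive the prediction only (no correction), so gaps are
filled with the filter's optimal estimate. Defaults `q = 0.01`, `r = 1`,
`init_cov = 1`, initial estimate = first observed value; all
configurable. The steady-state gain has the closed form
`K* = P*/(P*+r)` with `P* = (q + sqrt(q^2+4qr))/2` (Riccati fixed
point), which the tests use as an oracle; with `q = 0` the filter reduces
to recursive averaging with gain `P0/(r + n·P0)`.

The age-aware heart-rate flag uses lower bound 60 bpm (the conventional
bradycardia threshold) and upper bound `220 - age` (the conventional
age-predicted maximum); both configurable. Flagged records are retained
with the flag stored in an `hr_flag` column rather than dropped — the
flag marks records deserving attention, not invalid data. The
"irrelevant attribute" cleanup is a zero-variance column drop; anything
stronger is left to the wrapper selection stage.

## RL-SCSO

Candidate solutions are real vectors in `[LB, UB]^d`. Per iteration
`I = 1..Imax` the sensitivity range decays linearly,
`V_S = gamma - gamma·I/Imax` with `gamma = 2`, reaching 0 exactly at the
final iteration (so the last sweep is pure exploitation at the incumbent
best; the analytic schedule starts at `V_S(0) = gamma`). Each cat draws
a phase factor `U ~ Uniform[-V_S, V_S]` and a personal range
`V_range ~ Uniform[0, V_S]`, then moves by

* **exploit** (`|U| <= 1`): `Q' = Q_best - |r·Q_best - Q_cur|·V_range·cos(beta)`
  with `beta` drawn by a roulette wheel over a 1° grid of [0°, 360°]
  (uniform weights by default, custom weights supported), or
* **explore** (`|U| > 1`): `Q' = V_range·(Q_ocp - r·Q_cur)` where
  `Q_ocp` is a random member of the better half of the population
  (configurable to the global best).

Uniform draws `r` are taken per dimension. Positions are clipped to the
bounds after every move. After each sweep the refracted opposite of the
global best,

    T' = (LB+UB)/2 + (LB+UB)/(2·k·mu) - T/(k·mu),

is evaluated and the better of the pair kept (`k = mu = 1` by default,
giving reflection through the interval midpoint). The incumbent best is
the minimum over *all* evaluations, so the best-so-far trace is
non-increasing by construction.

### Wrapper feature selection

A continuous position maps to a feature mask by the sigmoid transfer:
bit j is set iff `position_j > 0`; an all-zero mask is repaired to the
single bit at the largest position. Bounds are `[-4, 4]` per dimension
(the sigmoid saturates outside). The subset fitness is

    Fit = lambda·delta + (1-lambda)·|S|/|Tf|,  lambda = 0.99 by default,

where `delta` is the stratified 5-fold cross-validated misclassification
rate of the wrapper evaluator on the masked columns — by default the
ensemble's cheapest member, AdaBoost with 50 stumps, under a fixed fold
seed so the fitness is a deterministic function of the mask. Fold
layouts and per-column sort orders are computed once and mask fitnesses
memoized, since the swarm revisits masks heavily.

Study sizes: the exhaustive-oracle comparison uses 8-feature cohorts of
n = 500 (large enough that the cross-validated error is a stable
landscape, so the study measures the optimizer rather than CV noise) with
swarm settings pop 20 / 60 iterations; the recovery and ensemble studies
use the generator defaults (n = 2000, 4 informative + 16 noise) with
pop 12 / 25 iterations, which keeps each full study in the minutes range
on one core.

## The boosters

**AdaBoost** — discrete two-class boosting of exact-search decision
stumps; stage weight `alpha_m = 0.5·ln((1-err_m)/err_m)`, multiplicative
weight update and renormalization; a round with weighted error >= 0.5 is
rejected and halts fitting (with a 1e-10 tolerance for accumulated
rounding), a perfect round is kept with a capped weight and halts.
Default 200 estimators.

**LogitBoost** — stagewise additive logistic regression. Each stage
computes working responses `z = (y* - p)/(p(1-p))` (clipped to ±4) and
weights `w = p(1-p)` (floored at 1e-10; probabilities floored at 1e-10),
fits a weighted-least-squares regression stump and adds a half Newton
step to the score `F`; `P(y=1|x) = 1/(1+exp(-2F))`. If a half step would
raise the training negative log-likelihood it is halved (up to 10 times)
and fitting stops when no improving step exists, making the NLL trace
non-increasing by construction. Default 100 stages.

**CatBoost-style booster** — gradient boosting on log-loss with
depth-limited *symmetric* (oblivious) trees: all nodes of a level share
one (feature, threshold) predicate, chosen greedily from quantile
histograms (32 bins) by the standard gain `G^2/(H+l2)` with Newton leaf
values `sum g/(sum h + l2)` and shrinkage. Categorical columns are
replaced by *ordered target statistics*: one random permutation is drawn
at fit time and each row's category is encoded as
`(prefix target sum + a·prior)/(prefix count + a)` over strictly earlier
rows in the permutation (prior = global positive rate, a = 1), so no
row's own label leaks into its encoding; prediction-time encoding uses
the smoothed full-training statistics. One permutation is shared by all
trees — a simplification of the multi-permutation scheme the full
library uses. Defaults: 500 trees, depth 6, learning rate 0.1, l2 = 3.

**Ensemble** — unweighted hard majority vote of the three members
(three binary voters cannot tie). The training protocol is a stratified
80:20 split under a seed, members trained on identical training data,
majority-vote evaluation on the held-out 20%, and optionally stratified
5-fold cross-validated metrics pooled over validation folds of the
training partition (`cv_folds=0` disables this when only held-out
accuracy is needed, as in the repeated-seed studies).

## Metrics

From confusion counts (explicit positive label): sensitivity,
specificity, accuracy, precision (= PPV), F1, NPV, FPR, FNR, and MCC.
Zero-denominator metrics return 0 with a `RuntimeWarning`. Identities
`sen + fnr = 1`, `spe + fpr = 1`, and F1 = harmonic mean(precision,
sensitivity) are property-tested over random count tuples.

## Numerical choices and degenerate inputs

* Stump search enumerates midpoints between distinct sorted values plus
  the constant stump (threshold +inf); ties in the split search resolve
  to the first minimal column/position, which makes label-flip symmetry
  exact for LogitBoost.
* Min-max normalization maps constant training columns to 0 and
  extrapolates (no clipping) outside the training range; the inverse
  transform recovers inputs to 1e-9.
* A one-feature table short-circuits selection to the only feasible
  subset; single-class tables are rejected everywhere with `ValueError`.
* All stochastic components consume `numpy.random.Generator` seeds
  recorded in configs; equal configs give byte-identical outputs.

## Known limitations

* Deep (ECG-embedding) features are consumed as precomputed vectors via
  CSV and concatenated after shallow-feature normalization; no encoder
  training is included.
* The CatBoost-style booster implements the core mechanisms (symmetric
  trees, ordered target statistics) but not the full library's
  multi-permutation averaging, feature combinations, or missing-value
  handling inside trees.
* The ensemble sanity studies compare medians over seeded replicates;
  individual seeds can show the vote trailing the best member by more
  than the median bound, which is expected for majority votes of
  correlated members.
* Wrapper selection cost grows with the mask-fitness cache miss rate;
  for dimensions well beyond ~30 the evaluator dominates runtime and
  smaller swarm budgets or a cheaper evaluator are advisable.
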