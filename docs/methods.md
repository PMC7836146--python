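# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Problem setting

Each pregnancy record carries 10 static predictors — maternal height (cm),
pre-pregnancy weight (kg), age (years), uterine (fundal) height (cm),
abdominal circumference (cm), and the fetal ultrasound measurements femur
length, fetal abdominal circumference, biparietal diameter, head
circumference (cm) and amniotic fluid index — plus an irregular series of
(gestational week, maternal weight) antenatal visits, parity, delivery week
and, for training data, the birthweight outcome in grams. Units are fixed
at the type level: maternal weights kg, birthweight g, lengths cm, weeks as
decimal completed weeks.

## Visit-series imputation

Antenatal visits happen at irregular weeks, so the temporal input is
standardized by fitting each woman's absolute weight series with a
quadratic polynomial P(t) minimising the residual sum of squares, then
evaluating the weight *change* P(t) − w at the six canonical weeks
20, 25, 30, 35, 37, 38. Fitting absolute weights and differencing
afterwards is algebraically identical to fitting changes (w is constant per
woman) but keeps the coefficients interpretable as a weight curve.

The minimiser is computed in closed form (the objective is an ordinary
least-squares problem); `numpy`'s polynomial fit on a centred/scaled week
variable is used for conditioning and converted back to raw-week
coefficients. Fewer than three distinct visit weeks leaves the normal
equations singular and raises an explicit error. Records qualify for
modelling only with at least 5 observed visits — also the practical minimum
for a stable quadratic — and at most 20 % of scheduled visits missing. The
scheduled count is a parameter (default 8) because a missingness fraction
needs a denominator, which raw visit lists do not carry.

## Normalization

All 16 features and the training label are min-max scaled to [−1, 1] with
y = 2(x − x_min)/(x_max − x_min) − 1, extrema learned on training rows
only. Test values beyond the training extrema are transformed then clamped
to [−1, 1]; the transform is undefined out of range and clamping keeps the
network's input domain bounded. Constant features are flagged and map to 0
by convention. Predictions are denormalized back to grams before any metric
is computed.

## The hybrid network

The weight-change series (6 scalars) feeds a stack of LSTM layers with the
standard three-gate cell; initial states are zero. The default geometry is
10 stacked layers of hidden width 2 with a scalar input per step, and the
recurrent features (x_h5, x_h6) are the two components of the top layer's
final hidden state. An alternate reading of the architecture — hidden
width 1, features taken from the top layer's output at the last two time
steps — is selectable (`mode="last_two_steps"`); both give the 12-long
dense input the 12 × 20 × 12 × 1 head requires. The dense head applies
ReLU between hidden layers, a linear output unit, and dropout 0.2 between
hidden dense layers during training only (inference is deterministic).
ReLU is applied to the two recurrent features before concatenation with
the 10 raw static features.

Training minimises MSE on the normalized label scale with mini-batch Adam
(batch 50, default learning rate 1e-3, uniform fan-in initialization,
forget-gate biases started at 1 for gradient flow — a standard recurrent
initialization). Two stop conditions: reaching `max_epochs`, or validation
MSE below the predetermined minimum error for 10 consecutive epochs
("threshold" mode; the threshold is never published, so the default is
1e-4 and configurable). A "plateau" mode — 10 epochs without validation
improvement — is available as the alternate interpretation. The trainer
snapshots parameters at the best validation epoch and restores them on exit
(`restore_best`, default on), standard early-stopping practice that
measurably reduces overfitting here. Gradients are hand-derived
backpropagation-through-time; a finite-difference test on a small network
pins every parameter gradient to < 1e-4 relative error. Divergence (a
non-finite loss) raises an error carrying the epoch index rather than
returning silently broken parameters.

A depth-10, width-2 recurrent stack is unusual and trains slowly; depth is
a configuration knob, and depths of 1–2 are recommended in practice (the
scaled-down experiments use depth 2).

## Baselines

* **Zhuo's formula**: grams = uterine height (cm) × 100. Training-free.
* **Linear regression**: OLS with intercept (scikit-learn). The 16-feature
  design is structurally rank-deficient — the six imputed series columns
  are generated by only three quadratic coefficients plus w — so the
  minimum-norm least-squares solution is used, with a logged warning.
* **SVR** (linear kernel, C = 1.0, tol = 1e-3) and **random forest**
  (200 trees, max_features 7) delegate to scikit-learn.
* **BPNN**: a 3-layer network (ReLU hidden layer, sigmoid output; labels
  rescaled into the sigmoid's range), Adam, 200 epochs, batch 128, built on
  the package's own network engine. The hidden width is not part of the
  reference configuration; 16 is used.
* **CNN**: two kernel-size-1, stride-2 convolution blocks (1→10 and 10→20
  channels) over the 16-feature vector treated as a 1-D single-channel
  signal, ReLU activations, linear readout, Adam at lr 0.01, 100 epochs.
  A kernel-1/stride-2 convolution is reproduced as configured even though
  it amounts to a strided pointwise channel mix and is likely a
  typographical artifact in the source configuration.

## Evaluation

MRE = (1/n) Σ |ŷ−y|/y; ±250 g accuracy counts |ŷ−y| **strictly** below
250 g; category accuracy compares SGA/AGA/LGA classes with SGA < 2500 g
and LGA > 4000 g — both published definitions are strict inequalities, so
the boundary weights 2500 g and 4000 g are assigned to AGA. Splits are
seeded: 80/20 train/test with train size round(0.8 n), and 5-fold CV with
fold sizes differing by at most one. Subgroup reports cross parity (first
delivery = parity 0 vs multiple) with delivery week binned by completed
week (floor) into < 39, 39, 40, > 40; empty subgroups are reported with
n = 0 and absent metrics. Metrics are fractions internally and formatted
as percentages (one decimal) in report tables.

## Synthetic cohort generator

Real obstetric EMR data of this kind is private, so the generator is the
package's study population; its defaults are the study conditions and are
not tuning knobs.

* **Static predictors**: truncated normals with the published cohort's
  mean/sd/min/max per predictor (e.g. height 160.4 ± 4.8 cm on
  [144, 184]). The published summary gives only marginals; a single latent
  "fetal size" factor with loading 0.5 on (w, uh, acp, bpd, acf, fl, hc)
  is planted so that uterine height genuinely predicts birthweight —
  without it the fundal-height baseline would be meaninglessly bad.
  Sampling rejects the idiosyncratic component until the value falls in
  range (clamping as a last resort), preserving the latent structure.
* **Weight trajectory**: weight(t) = w + g(t−4) + c(t−4)², with per-woman
  gain rate g (mean 0.0498 kg/wk, sd 0.03, loading 0.4 on the latent
  factor) and curvature c (mean 0.01056 kg/wk², sd 0.002). The rate/
  curvature means solve the published mean gains at weeks 20 (3.5 kg) and
  38 (13.9 kg) exactly; intermediate weeks then deviate from the published
  means by ≤ 0.9 kg, the cost of a single quadratic family. Eight visits
  are scheduled from week 8 to just before delivery, jittered (sd 0.7 wk),
  observed with 0.4 kg measurement noise, and dropped independently with
  probability 0.10 (missing completely at random — the true visit-count
  distribution and missingness mechanism are unpublished assumptions).
* **Outcome**: birthweight = 3398.06 + Σ βⱼ·z(predictorⱼ) +
  β_gain·z(total gain at week 38) + ε, ε ~ N(0, 244), clipped to
  [1520, 4950] g. The β (per-sd grams; uh and gain 117.7, acf 84.1, bpd
  67.3, hc 50.4, w/acp/fl 33.6, h/afi 16.8, age 0) were derived once by
  moment-matching simulation (`scripts/calibrate_outcome.py`) so the
  marginal matches mean 3399.1 g / sd 385.8 g with planted signal
  R² ≈ 0.6, and are frozen as named constants.
* **Other fields**: delivery week ~ truncated N(39.4, 0.9) on [37, 44];
  parity ~ Bernoulli(0.4).

Equal configs and seeds reproduce cohorts bit-for-bit; a single pipeline
seed derives per-stage seeds by hashing, so stages can be rerun
independently with identical behaviour.

## What the synthetic experiments do and do not show

The generator reproduces marginal moments, visit irregularity, missingness
and a learnable signal, which is enough to verify the pipeline's equations,
filters, training dynamics and metrics. It does **not** emulate real
obstetric data's nonlinearities, measurement artefacts, informative
missingness, or cohort heterogeneity. One consequence is worth stating
plainly: because the planted outcome is *exactly linear* in the predictors,
ordinary least squares is essentially the optimal predictor on this
population, and the hybrid network — like any flexible model — pays a small
estimation-variance penalty (≈ 2 accuracy points at n = 2000). Published
results on real hospital data show the opposite ordering; synthetic
benchmarks here bound correctness, not real-world ranking.

## Problem sizes

Defaults used by the shipped experiments: calibration cohort n = 5759;
scaled-down prediction study three cohorts of n = 2000 with depth-2
recurrent stack, ≤ 200 epochs; imputation error measured on 1000 records.

## Known limitations

* No uncertainty quantification on predictions or metrics.
* The quadratic family cannot capture non-monotone weight trajectories
  (e.g. late-pregnancy weight loss followed by regain beyond what a
  parabola allows).
* MCAR missingness is an assumption of convenience.
* "More than five antenatal examinations" is read inclusively (≥ 5
  observed visits); the alternative reading (≥ 6) would shift eligibility
  marginally.
* Twin pregnancies, complications and longitudinal ultrasound series are
  out of scope; ultrasound biometry enters as a single measurement per
  pregnancy.
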