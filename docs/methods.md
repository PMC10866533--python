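# Methods

This note documents the modeling choices behind `glucostack`: what each
stage assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Problem setting

Continuous glucose monitors report interstitial glucose (mg/dL) at a nominal
5-minute cadence. The forecasting task is univariate: given the last h
readings (h ∈ {6, 9, 12, 18} points, i.e. 30–90 minutes of history), predict
the next p readings (p ∈ {6, 9, 12}, i.e. a 30/45/60-minute prediction
horizon, "PH"). Metrics are computed on the final horizon step — the value
PH minutes ahead — with the intermediate steps serving as auxiliary training
targets; a horizon-averaged option exists but is not the default, since the
clinical question is "where will glucose be PH minutes from now".

## Preprocessing

Stages run in a fixed order — gap-fill → Kalman → smoothing → normalize →
split — enforced by provenance stamps when `strict=True`. All stages are
length-preserving after gap-filling.

**Gap filling.** Training series may use both neighbours of a gap (linear
interpolation); test series are filled strictly causally, each missing point
extrapolated from the two most recent observed-or-filled values, so no future
information leaks into test inputs. Timestamps are snapped to the 5-minute
grid anchored at the series start (real sensor clocks jitter by seconds;
windowing requires exact adjacency).

**Kalman filter.** A scalar forward filter (no backward smoothing pass) with
state transition A = 1, observation map H = 1:

    x̄ = A·x̂ + B·u        P̄ = A·P·A + Q
    K = P̄H / (HP̄H + R)   x̂ = x̄ + K(z − Hx̄)    P = (1 − KH)P̄

Defaults Q = 0.1 (mg/dL)², R = 4.0 (mg/dL)² model ≈2 mg/dL sensor noise over
a slowly drifting physiological signal; x₀ defaults to the first observation
and P₀ to R. Both are exposed in `KalmanConfig` — the appropriate Q/R ratio
depends on the sensor generation. The control term B·u is retained in the
config for completeness but defaults to zero (no insulin/meal inputs). For
A = H = 1 the error covariance P decreases monotonically to the fixed point
of the scalar Riccati recursion (verified numerically in the tests).

**Double exponential smoothing.** Holt's level/trend recursion with
α = 0.1, β = 0.5 and output Y′_t = L_t + T_t. Initialization is
L₁ = Y₁, T₁ = Y₂ − Y₁, chosen so that a linear series is exactly invariant:
for Y_t = at + b the output is Y_t + a. Note the output L_t + T_t is a
one-step-ahead quantity; it is applied as written, without re-alignment, so
the smoothed series carries an implied one-step lead. Smaller α smooths more
aggressively; β = 0.5 lets the trend react quickly to direction changes.

**Normalization.** Min–max bounds are fitted on the training series only and
applied to both splits; test values outside [0, 1] are deliberately not
clipped. Fitting on anything with role `test` raises.

**Split.** The windowed training samples are split chronologically, the last
20% (floor rule) forming the validation set. A chronological split avoids
the temporal leakage a random split would introduce between overlapping
windows.

Normalization is applied to the series before windowing; the two orders are
algebraically identical for min–max scaling, and normalizing first keeps the
window matrices on one scale.

## Base learners

Three recurrent architectures share one numpy core (`glucostack.nn`):
a bidirectional LSTM (128 units per direction, relu cell activation), a
stacked LSTM (128 → 64 → 32, linear activation) and a peephole "vanilla"
LSTM (128 units, linear activation; the gates additionally observe the cell
state — c_{t−1} for the input/forget gates, c_t for the output gate). The
cell activation φ applies to both the candidate and the cell output
(h_t = o_t ⊙ φ(c_t)); relu in place of the classical tanh is an intentional
property of the bidirectional variant, with tanh available via config. The
final recurrent layer emits its last hidden state into a linear dense head
of width p (vector multi-step output); earlier stacked layers pass full
hidden sequences.

The numpy core implements exact analytic backpropagation through time,
verified against central finite differences to ~1e-6 relative error for all
layer variants. Training uses Adam (lr 0.001, β₁ 0.9, β₂ 0.999), minibatches
of 32 shuffled per epoch, mean-squared-error loss, a global gradient-norm
clip at 5.0 (linear-activation cells are otherwise prone to occasional
spikes), up to 500 epochs with early stopping on validation loss
(patience 10) and best-weight restoration. Forget-gate biases initialize
to 1; other weights are Glorot-uniform from a per-model seed fanned out of
the master seed. Parameters are float32; inference is deterministic given
trained weights, and training is repeatable on the same machine (bitwise
reproducibility across BLAS builds is not promised).

**Profiles.** The `paper` profile is the full-size configuration above. The
`fast` profile — bidirectional [32], stacked [32, 16, 8], vanilla [32],
batch 64, ≤12 epochs, patience 3 — is the package's desk-scale choice for
test suites and the acceptance script, where dozens of fold models are
trained per run. It trades accuracy for tractability on a single CPU;
reported desk-scale numbers should be read as properties of the pipeline,
not as the full-size models' accuracy ceiling.

## Adaptive weighting

Validation samples are embedded in base-model prediction space: sample j
becomes the m-vector of the m base models' fold-averaged predictions at the
final horizon step. This is the one reading under which the cluster-variance
formula is well-defined (indices j over samples within clusters, k over
models, μ_{i,k} cluster means); clustering "the models themselves" (m points
of dimension n) is available as a config variant but is not the default.

The similarity between samples i and j is

    S_ij = −dis_ij − α·(var_i + var_j),     α = 0.5 by default,

where dis is the Euclidean distance and var_i the variance of point i's own
coordinates. Since var is constant per point, the α term lowers the
preference-relative similarity of samples on which the base models disagree,
nudging them away from exemplar roles. α is exposed in config; no canonical
value exists.

Affinity propagation runs on the precomputed S with the preference set to
the median off-diagonal similarity, damping 0.5, ≤200 iterations and a
convergence window of 15. Message passing is a fixed-point iteration that
can settle in a suboptimal labeling, so the algorithm is run at a short
damping ladder (0.5, 0.7, 0.9) and the exemplar set with the highest net
similarity — the objective AP itself maximizes — is kept; for n ≤ 64 a
greedy add/remove/swap local search on the same objective polishes the
result (ties break toward the lowest index). At most `sample_cap = 500`
validation points are clustered (seeded subsampling beyond that). If no
damping converges, the points collapse to a single medoid cluster and the
assignment is flagged.

Model k's raw score is its cluster-variance sum

    w_k = Σ over clusters i of (1/C) Σ_{j∈cluster i} (x_{j,k} − μ_{i,k})²,

normalized to sum to 1. As printed this upweights high-variance models; the
directionality is debatable, so an `invert_flag` maps w → 1/(w + 1e-8)
before normalizing (smaller within-cluster variance ⇒ larger weight). The
default is the literal form (invert off). An all-zero score vector yields
uniform weights with a warning. A caveat for the inverted mode: "low
within-cluster variance" rewards predictors whose errors add variance on top
of the truth less than their peers'; a heavily smoothed (over-regularized)
predictor can score better than an exact one, because smoothing also removes
the target's own within-cluster spread.

## Stacking

Per history window: 5-fold cross-validation over the training subset with
contiguous, non-shuffled folds (remainder samples go to the earliest folds),
respecting temporal ordering. Each architecture's fold model predicts its
held-out fold, giving exactly one out-of-fold prediction per training sample
per architecture; all 5 × m fold models are retained. The global validation
subset drives early stopping in every fold.

The meta-learner is ordinary least squares with intercept, one linear map
per horizon output, fitted on the fixed block order
[base₁ … base_m | weighted combination | original history window]
(h + (m+1)·p columns). Rank-deficient designs fall through to the lstsq
pseudoinverse with a warning. At test time each architecture's five fold
models predict the full test set and are averaged elementwise; the same
weights and meta-model produce the stacked forecast, which is denormalized
before scoring. One meta-model is fitted per history window (feature widths
differ across windows); the final report averages the four windows.

Test targets never reach base-model training, normalizer fitting, weight
estimation or the meta fit. A published variant of this architecture feeds
the initial *testing* set into the meta-estimator's training; that cannot be
done without target leakage and is not implemented here.

## Evaluation

RMSE and MAE in mg/dL. MCC is computed on the binary adverse-event mapping
of the IDF glycemic bands — low (<70), normal (70–<126), high (≥126 mg/dL);
low and high are "adverse" — with the 0 convention when a denominator factor
vanishes. Clarke error-grid zones follow the canonical 1987 predicates,
evaluated in the precedence A → E → C → D → B; the exact rule table ships as
JSON (`glucostack/data/clarke_zones.json`) so variants (e.g. Parkes-style
grids) can be swapped without code changes. Error-band fractions report the
share of predictions within ±10% and ±20% of the reference.

## Synthetic data

The generator produces baseline + circadian sinusoid (peak ~16:00) + meal
excursions (difference-of-exponentials pulses, 20-min rise / 90-min decay,
at homogeneous-Poisson meal times) + AR(1) sensor noise, clipped to the
40–400 mg/dL sensor range, with a Bernoulli fraction of readings dropped.
Defaults — 120 mg/dL baseline, 15 mg/dL circadian amplitude, 3 meals/day
peaking 80 mg/dL above baseline, 5 mg/dL noise with lag-1 autocorrelation
0.5, 2% missing — describe a plausibly controlled T1D subject whose trace
regularly crosses the 126 mg/dL band boundary, so band-classification
metrics are non-degenerate.

Not emulated: insulin and carbohydrate dynamics, exercise, sensor drift and
recalibration jumps, day-to-day nonstationarity, or hypoglycemic excursions
under the default settings. Passing tests therefore demonstrate that the
pipeline's machinery is correct and leak-free on data with realistic scale
and autocorrelation — not that the trained models reach clinical accuracy
on real CGM traces.

## Problem sizes in the test suite and acceptance script

The end-to-end checks use a 2000-point synthetic series (≈6.9 days; first
1600 points train, last 400 test) under the `fast` profile, three seeds for
the stochastic stacking-dominance check and one seed per horizon in the
acceptance script. Structural checks (fold coverage, meta-feature layout,
leakage audits) run with a cheap linear base learner, since they test
bookkeeping, not learner capacity. The exhaustive affinity-propagation
oracle enumerates all exemplar subsets up to n = 8.

## Known limitations

- The forward Kalman filter and the one-step-ahead smoothing output slightly
  lag fast excursions; an RTS smoother is out of scope by design.
- The weighted-similarity α and the invert flag lack principled defaults;
  both are exposed and should be tuned per deployment.
- Weights are estimated once per (PH, history window) run from validation
  samples and reused at test time; no online re-weighting.
- Desk-scale recurrent networks underfit relative to the full-size profile;
  the OLS meta-model (which also sees the raw history window) then carries
  most of the accuracy, which is visible in the stacked-to-best-base RMSE
  ratios well below 1.
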