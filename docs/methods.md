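# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `vo2pipe`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Kinetic models

Both V̇O₂ models are explicit (forward-Euler) steppers on the irregular
breath grid, which makes them directly usable on breath-by-breath data and
trivially restartable per session.

* **Model 1** is a single first-order lag toward `V̇O2R + G·P` with time
  constant τ. Defaults used in tests (G = 10 mlO₂·min⁻¹·W⁻¹, τ = 45 s) are
  typical of trained cyclists.
* **Model 2** splits the response into a fast (phase-II) and a slow
  (phase-III) component. The fast forcing is `min(s·P, V̇O2MAX − V̇O2R)`;
  the slow forcing is `V̇Δ·exp(−(Pc−P)/Δ)` below the critical power `Pc`
  and the complement `V̇O2MAX − V̇O2R − A_fast` above it, so sustained
  supra-critical work saturates the aerobic range. Each component is held
  at zero until the session clock passes its activation delay (T_fast,
  T_slow).

Numerical choices:

* **Euler stability guard.** The simulators raise if any breath interval
  reaches `2·min(τ)`; physiological breath intervals (0.7–5 s) are far
  below the bound for all admissible time constants (τ ≥ 10 s).
* **Activation-delay semantics.** The forcing of a delayed component is
  held at zero until the clock reaches the delay, after which normal
  first-order dynamics apply — a delayed onset, with no retroactive jump.
* **Delay clock origin.** The clock starts at exercise onset (the first
  breath with non-zero power), not at the start of the recording, and is
  overridable (`onset_time`). Global session time is used in the
  activation test rather than time since the most recent power transition;
  the alternative reading would re-arm the delays at every interval change,
  which contradicts the usual delayed-onset-exponential formulation.
* **Fixed points are preserved bit-exactly**: feeding a component its own
  steady state returns it unchanged, which the tests assert.
* Model 2's output is bounded in `[V̇O2R, V̇O2MAX + V̇Δ]` for bounded
  power; the small overshoot allowance comes from the sub-critical slow
  forcing at `P = Pc`.

## Synthetic athletes and sessions

The generator produces the study conditions the analysis assumes, so every
downstream stage is testable without human data.

**Cohort.** Weight (76.0 (6.6) kg) and PPO (335 (44) W) are Gaussian.
Threshold powers are drawn as fractions of PPO — `P_VT2/PPO ~ N(0.818,
0.05)`, `P_VT1/P_VT2 ~ N(0.796, 0.08)` — and V̇O2MAX as a per-watt ratio
(`N(13.26, 1.2) mlO₂·min⁻¹·W⁻¹ × PPO`). Correlated draws are the
physiologically realistic choice (fitter athletes have uniformly higher
anchors) and reproduce the population marginals (V̇O2MAX ≈ 4443 (710)
mlO₂·min⁻¹; P1/P2/P3 means 109/246/304 W) without the truncation bias that
independent draws plus the ordering constraints `P_VT1 < P_VT2 < PPO` would
introduce. The intensity levels follow `P1 = P_VT1/2`,
`P2 = (P_VT1+P_VT2)/2`, `P3 = (P_VT2+PPO)/2`. Resting V̇O₂ is
3.5 mlO₂·min⁻¹ per kg body mass plus noise; RF anchors ~14/55 min⁻¹, HR
anchors ~58/190 min⁻¹, Wingate peak power 2.2·PPO, maximal cadence
~120 rpm — values chosen once as typical of amateur road cyclists.

**Ground-truth kinetics.** Each athlete carries a private Model 2 parameter
set (`true_m2`) jittered around published cycling estimates (V̇Δ 400 (80)
mlO₂·min⁻¹, Δ 79 (15) W, s 8.67 (0.4) mlO₂·min⁻¹·W⁻¹, τ_fast 43 (3) s,
τ_slow 199 (30) s, T_fast 10 (3) s, T_slow 113 (20) s) with
`Pc = 1.07·PPO` (critical power slightly above peak graded-test power).
Draws are rejected (in an inner loop, so the anchor distributions are not
biased) unless the slow-component residual at zero power,
`V̇Δ·exp(−Pc/Δ)`, stays below 1.5% of V̇O2R — the ground truth must be
consistent with the athlete's own resting value.

**Sessions.** Four protocols: a GXT (100 W + 40 W per 4-min stage, ending
partway through the stage containing the athlete's PPO so the
completed-stage interpolation recovers it exactly); Test 1 (4 min at 100 W,
then 3 × 4-min bouts at P2, P3, P1); Test 2 (a prescribed sequence of ramps
and constant bouts between P1 and P3); and a 30-s all-out Wingate sprint,
modelled as a linear decay from the athlete's peak sprint power to 70% of
it (a typical fatigue index), framed by 120 s of rest and 300 s of unloaded
recovery so recovery kinetics are observable. The full laboratory-visit
structure is generated: 4 min of seated rest (used for the resting
averages) and a 10-min warm-up at 85 W precede the GXT, and the interval
protocols are preceded by the warm-up and a 4-min rest. The warm-up/rest
lead-ins matter beyond realism: they give the training sets exercise→rest
transitions and resting targets with full 70-breath input windows, without
which post-sprint recovery would be entirely outside the training
distribution of the Trial-2 regressor.

**Breath timing and channels.** RF follows a first-order response (τ =
35 s) toward a power-proportional target between the athlete's resting and
maximal RF; breath times are laid down sequentially with inter-breath
interval 60/RF, so timing irregularity is itself intensity-dependent. V̇O₂
at the breath times integrates the athlete's `true_m2` dynamics plus
additive Gaussian noise (default SD 150 mlO₂·min⁻¹, of the order of
breath-by-breath measurement noise at high intensity). HR is a first-order
response (τ = 30 s) between its rest/max anchors. Ventilation tracks V̇O₂
(ventilatory equivalent ≈ 24), and expired O₂/CO₂ fractions drift with
relative intensity inside the analyser validity ranges. A configurable
fraction of breaths is corrupted to violate those ranges
(RF 2–90 min⁻¹, VE 0.1–10000 L·min⁻¹, FeO₂ 5–20%, FeCO₂ 1–10%) to
exercise the validity filter. The VE range is implemented as given, on
L·min⁻¹; it is wide enough that the unit reading is inert.

What the generator deliberately does **not** contain: cardiovascular drift,
intensity-dependent gains or time constants beyond Model 2's structure,
cadence effects on V̇O₂ (cadence is constant at 90 rpm outside the sprint),
day-to-day HR variability, and any HR/RF information about V̇O₂ beyond what
power history already carries (both are driven by the same power signal).
Consequently, passing tests show that the pipeline machinery and the
learning procedure work under the assumed data-generating process; they do
not show that the regressor captures physiological structure absent from
that process.

## Dataset preparation

Invalid breaths are removed first. The uniformly sampled power/cadence
trace is resampled to the breath grid by interval means over
`(t_{k-1}, t_k]` (gas values are themselves interval aggregates; the first
breath takes the nearest sample). Channels are normalized linearly between
anchors measured from the athlete's own GXT — V̇O₂: (V̇O2R, V̇O2MAX), RF:
(RF_rest, RF_max), power: (0, PPO), cadence: (0, ω_max), HR: (HR_rest,
HR_max) — with no clipping anywhere, so supra-maximal sprint values exceed
1 legitimately. HR has no laboratory-defined anchor convention; rest-to-max
normalization was chosen for symmetry with RF. Windows of n = 70 breaths
(channel order P, ω, HR, RF) predict the next breath's normalized V̇O₂; a
session of N breaths yields N − 70 samples, and windows never cross session
boundaries. Trial 1 trains on {GXT, Wingate, Test 2} and tests on Test 1;
Trial 2 trains on {GXT, Test 1, Test 2} and tests on the Wingate. All
datasets are per athlete; no pooling across athletes.

## Calibration

The objective is the sum of squared residuals over all training breaths,
with the simulation restarted from rest at each session. Out-of-bounds or
ordering-violating parameter vectors receive a large graded penalty rather
than an exception, so the optimizer can probe freely. The optimizer is a
global-best particle swarm: 40 particles (common practice at 2–8
dimensions), constriction coefficients (inertia 0.729, cognitive = social
= 1.494), 250 iterations, positions reflected at the box bounds. Bounds:
G ∈ [5, 15], τ ∈ [10, 120] for Model 1; Model 2 bounds bracket published
cycling estimates (e.g. Pc ∈ [200, 500] W, τ_slow ∈ [60, 400] s). The
swarm objective is evaluated through simulators vectorized over parameter
rows (one breath loop serves the whole swarm); tests assert bitwise-level
agreement with the scalar steppers. V̇Δ and Δ are weakly identified when
the training data rarely approach Pc; recovery experiments therefore gate
only G and τ (Model 1) and the well-identified fast-phase parameters.

## Regressor

Architecture per the study design: LSTM(32, sequences) → LSTM(32,
sequences) → LSTM(32, last state) → dense(10, leaky ReLU) → dense(1, linear);
4·(d_in+units+1)·units parameters per LSTM layer and d_in·units+units per
dense layer, totalling 21 717. Training: Adagrad, batch 10, 20 epochs
(reduced in desk-scale experiments), samples shuffled each epoch, weights
from seeded Glorot-uniform initializers and biases initialized to small
random positive values. The published recipe names a categorical
cross-entropy loss, which is not computable for a scalar regression
target; the default loss is mean squared error, with a
binary-cross-entropy-on-[0,1] option (sigmoid output) to mirror the
plausible intent. The learning rate (0.05) is an implementation choice:
Adagrad's effective step decays as squared gradients accumulate, and a
larger base rate lets 20 shuffled epochs reach the noise floor on datasets
of a few thousand windows. The global gradient norm is clipped to 1.0 to
survive the all-out sprint segments. Batch size is a free dimension at
inference. The implementation is self-contained (numpy arrays throughout,
with the recurrent time-stepping kernels compiled by numba); a fixed seed
gives bit-identical training runs.

## Evaluation

Residuals are measured − predicted. Absolute errors come from
range-denormalized values (the [V̇O2R, V̇O2MAX] span); percentage errors
divide the absolute error by V̇O2MAX — the only reading consistent with
reporting both `%V̇O2MAX` and mlO₂·min⁻¹ variants of the same number.
Bland-Altman: bias = mean difference, LoA95 = 1.96·SD, and a t-based
confidence interval on the bias (sessions are small samples); the bias is
flagged when zero lies outside the CI, and flagged as beyond the meaningful
limit when the whole CI lies outside ±200 mlO₂·min⁻¹ (a level comparable
to breath-by-breath noise at high intensity). The residual ACF uses the
standard statsmodels estimator with white-noise bands ±z₀.₉₇₅/√n and
reports the fraction of lags outside the band; max_lag defaults to
min(n/4, 100). A slope-vs-mean proportional-bias diagnostic is not gated.

**Prediction alignment.** The network can only predict breaths
n+1 … N of a test session (it needs a full input window), so the pipeline
scores every predictor — including the kinetic models — on that same
breath subset. On the Wingate session this means the evaluated stretch is
dominated by post-sprint recovery; Pearson r is accordingly low for all
predictors there (the recovery tail is nearly flat relative to the noise)
while MAE remains the informative metric.

## Orchestration and reproducibility

All randomness derives from one master seed through
`numpy.random.SeedSequence(entropy=master, spawn_key=(athlete, stage,
index))`, so adding athletes never perturbs existing ones, and a rerun of
the same configuration is bit-identical. Per-cell failures are recorded
with their reason and never abort the remaining cells. When an output
directory is configured, PSO fits are cached on disk keyed by a hash of
the configuration, and the per-athlete and group tables are written as CSV.

Desk-scale experiment sizes: the end-to-end study in the test suite uses 2
athletes, both trials, 6 training epochs and 3 master seeds; the parameter-
recovery experiment uses 10 seeds of a 500-breath varied-intensity session
with noise SD 50 mlO₂·min⁻¹. These sizes were chosen so the full suite
runs comfortably on a laptop-class single core while keeping every
statistical check well-powered.

## Known limitations

* The generator's V̇O₂ is conditionally independent of HR/RF given power
  history, so the regressor's advantage over the kinetic models is
  structurally smaller here than on real data; orderings, not magnitudes,
  are the meaningful comparisons.
* Ventilatory-threshold identification is a manual gas-exchange procedure
  and is out of scope; threshold event times (or powers) are inputs.
* No cardiovascular drift or prolonged-exercise effects; sessions are
  ≤ ~1 h and the models assume stationary parameters.
* Group tables average per-athlete metrics (mean (SD) across athletes);
  residuals are never pooled across athletes.
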