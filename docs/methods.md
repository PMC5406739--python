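# Methods

This note documents the models implemented in `mtmdecode`, the
conventions and numerical choices behind them, what the synthetic-session
generator does and does not emulate, and the known limitations.

## Task and conventions

The task is delayed obstacle-avoidance reaching on a 20 × 20 cm
workspace centred at the origin: four canonical positions (bottom, left,
top, right at ±8 cm), a trial running start → target around a rectangular
obstacle centred on the straight start–target segment, with an opening on
one side (clockwise or counterclockwise pass).  The full condition
catalogue is 4 starts × 3 targets × 2 openings = 24; fixing the start
leaves 6 movement regimes, numbered `regime_id = 2·target_index +
opening_index + 1` with targets in canonical order and openings ordered
(clockwise, counterclockwise).  That numbering is the package-wide
ordering of regime priors and mixture weights.

Time is binned at 100 ms.  A trial is rest (5 bins), delay 1 (3 bins,
target visible), delay 2 (5–8 bins, obstacle visible), movement (10–15
bins) and hold (5 bins); epoch ranges are half-open, 0-based bin indices.
Spike counts are non-negative integers per bin; positions are cm.

## Regime state-space models

Each regime `m` has a linear-Gaussian state-space model with a
position-only state: `x_t = A_m x_{t-1} + b_m + w`, `w ~ N(0, Q_m)`, and
`y_t = H_m x_t + p_m + v`, `v ~ N(0, V_m)`.  No velocity augmentation is
used; the state is literally the 2D hand position.

Fitting conventions:

* Dynamics are fitted by least squares in *increment form*: the position
  change `x_t − x_{t-1}` is regressed on `[x_{t-1}, 1]` and `A = I +
  slope`.  At full rank this equals regressing `x_t` on `x_{t-1}`; when
  the design is rank-deficient (e.g. constant positions) the minimum-norm
  pseudo-inverse yields the random walk `A = I, b = 0`, which is the
  documented degenerate-input behaviour.  `Q` is the maximum-likelihood
  residual covariance, symmetrised.  Fewer than 4 transition pairs is an
  error (underdetermined).
* Observations are per-unit least squares of counts on `[x, 1]`.  `V` is
  fitted **diagonal** by default: with ~40 units and ~40–50 trials per
  regime a full 40 × 40 covariance is ill-conditioned, and a diagonal `V`
  matches the unit-independence assumed by the delay-window classifier.
  A full-covariance option exists.  Diagonal entries are floored at 1e-6
  so silent units cannot produce a degenerate density.
* Regimes are keyed per start position — `(start, target, opening)`
  (M = 6 per start) or `(start, target)` (M = 3).  Each regime needs at
  least `min_trials = 5` trials; a missing regime raises an error naming
  it.  The initial state `x_0` is the empirical mean/covariance of
  movement-onset positions across training trials (covariance floored by
  1e-6·I).

## Mixture decoding

Decoding runs M regime-conditional filters in parallel from the shared
initial state.  Because each regime's model is linear-Gaussian, the
regime-conditional posterior is exact (the generic Gaussian approximation
matching location and curvature reduces to the Kalman update); the
measurement update uses the Joseph form and a Cholesky solve of the
innovation covariance.  Mixture weights combine a regime prior `P(m)`
with the accumulated per-bin log innovation likelihoods
`log N(y_t; H μ_pred + p, H P_pred Hᵀ + V)`; accumulation is in the log
domain with max-subtraction before normalisation, since products of
per-bin likelihoods over ~40 units underflow within a few bins.

Two weight-update modes exist.  The default, `likelihood`, updates
weights every bin with the accumulated evidence (`w_m(t) ∝ P(y_1..t|m)
P(m)`), which is the literal reading of the recursion; `static` pins the
weights at the prior for the whole movement, as an ablation of whether
evidence or prior carries the comparison.  The reported collapsed mean
and covariance are the exact mixture moments.  Credible intervals are
per-coordinate, `mean ± z·√diag(cov)` at the configured level (default
95%).  Decoding is causal filtering only; no smoothing.

## Delay-window prior decoding

Features are per-unit **mean counts over a fixed window** (one number per
unit, not concatenated bins): the target window is rest + delay 1 + the
first delay-2 bin (9 bins at default epoch lengths — the extra bin
absorbs the causal response latency), the selection window is delay-2
bins 2–5 (4 bins, 100–500 ms after obstacle onset).  The classifier is
per-unit Gaussian Bayes with class-conditional sample means and
maximum-likelihood variances, a uniform class prior (classes are
presented equally often by task design), log-domain evaluation, and a
variance floor of 1e-4 (silent units).  Chance levels are fixed at 1/3
(three targets) and 1/2 (two openings).

Evaluation is leave-one-out: for each trial the classifier is refitted
on all other trials and the posterior probability assigned to the true
class is recorded.  The primary statistic is this mean posterior
("expectation of selecting the right class"), with hard-classification
accuracy reported alongside, plus a two-sided one-sample t-test of the
per-trial expectations against chance.

The two posteriors combine under independence into the 6-regime prior,
`P(m) = P(target) · P(opening)` mapped through the catalogue bijection.
The target-only decoder expands the 3-class target posterior over 6
regimes by splitting each target's mass equally across its two openings
(keeping M = 6 models so all three decoder conditions share the same
fitted models; using M = 3 target-keyed models directly is supported as
an alternative path).

## Population analyses

The population vector (PV) uses velocity tuning fitted on movement
epochs: per-unit regression of counts on `(v_x, v_y)` with intercept,
velocities being first differences of position over the 0.1 s bin.
Coefficient vectors are deliberately **not** normalised, so strongly
tuned units carry more weight.  The PV of a bin is
`Σ_i (rate_i − baseline_i)·c_i` with `baseline_i` the unit's rest-epoch
mean rate.  The baseline subtraction is this package's choice (the exact
weighting is not standardised): it makes rest-epoch PVs fluctuate around
zero so that delay-onset modulation stands out, which is the behaviour
the analysis is meant to expose.  The PV evolution of a condition sums
PVs over 20 trials across 9 pre-movement bins (5 rest + 3 delay 1 +
first delay 2).

The delay-2 PCA takes every 100 ms bin of the selection window as one
sample (not trial averages), mean-centres, and projects onto the top two
components.  Cluster separation between the two intended selections is
only clean within a fixed start–target pair; pooling targets mixes three
initial-direction clusters per class and blurs the picture.

## Evaluation

CC is the per-coordinate Pearson correlation between decoded and true
movement trajectories, averaged over x and y; a zero-variance coordinate
is excluded with a warning.  MSE is the mean squared Euclidean error per
bin computed on workspace coordinates normalised to [0, 1] per axis (so
sessions and workspaces are comparable; raw-cm scoring is available by
skipping normalisation).  Success requires (a) no segment of the decoded
path intersects the obstacle rectangle (exact segment–box test via
shapely) and (b) the final decoded point lies within the 2 cm target
radius.  No hold-period criterion is applied to decoded trajectories:
offline decoding has no dwell dynamics at the target, so
endpoint-within-radius is the meaningful completion test.

The three-decoder comparison is leave-one-out end to end: for each held
trial, regime models *and* both delay-window classifiers are trained on
the remaining trials, and the trial is decoded under the uniform, target
and combined priors.  Conditions are compared with two-sided paired
t-tests per metric and percentage changes in the ascending/descending
convention: CC and success as `(new − old)/old · 100`, MSE as
`(old − new)/old · 100`.

## Synthetic sessions

No recordings for this task are publicly deposited, so the generator
produces sessions with exactly the statistical structure the pipeline
assumes, at sizes matching the real experiment (defaults 40 units; the
benchmark sessions used throughout the tests and the acceptance script
are 240 trials over the 6 regimes of one start position, which keeps the
full leave-one-out three-decoder comparison at a few seconds).

Each unit has a baseline rate (uniform 2–6 counts/bin) and a 2D
velocity-tuning vector `c_i` with uniform random direction and magnitude
0.02–0.10 counts/(cm/s) — at the task's 15–30 cm/s movement speeds this
modulates rates by up to ~3 counts/bin, a moderate single-unit SNR.
The epochs are generated as:

* **Rest**: Gaussian counts at baseline (SD 1.2).
* **Delay 1**: class-conditional Gaussian with mean `baseline +
  g₁ (c_i · u_target)`, `g₁ = 12 cm/s` — the population behaves as if
  already driving a planned movement toward the target.
* **Delay 2**: mean `baseline + g₂ᵗ (c_i · u_target) + g₂ˢ (c_i ·
  u_initial)` with `g₂ᵗ = 1`, `g₂ˢ = 6 cm/s`, where `u_initial` points
  from the start toward the obstacle opening.  The selection signal
  dominates; the small residual target term is deliberate, because a
  large one makes the per-opening class distributions strongly
  multimodal (mixtures over targets), violating the Gaussian class model
  and producing confidently wrong selection posteriors.
* **Movement/hold**: counts follow the regime's linear-Gaussian
  observation model `y = H_m x + p_m + ε`, `ε ~ N(0, 4.5²·I)`.  The
  per-regime `(H_m, p_m)` are derived from the same velocity tuning by
  projecting it onto position along the regime's noise-free reference
  path (`v ≈ B_m x + a_m` by least squares, so `H_m = C·B_m`, `p_m =
  baseline + C·a_m`).  Counts are therefore exactly linear-Gaussian in
  position within a regime — the fitted model is well-specified — while
  regimes differ in their observation maps the way velocity-tuned
  populations do; in particular the expected rates at the shared start
  position already reflect each regime's initial movement direction.

Hand paths are quadratic Bézier curves through a via point 4 cm to the
side of the obstacle (clearing it by construction at zero noise), with a
minimum-jerk time profile, plus 0.3 cm white positional noise;
pre-movement positions jitter by 0.15 cm around the start.  Counts are
rounded and clipped at zero by default; the Gaussian rate model is then
applied to these integer counts exactly as the analysis does on real
spike counts.  With `integer_counts=False` the raw Gaussian draws are
returned, for which the configured means/variances are exact — parameter
recovery and law-of-large-numbers tests use this mode, since clipping
biases low-rate units.

The delay SNRs were set so that leave-one-out expectations land in a
realistic range (targets ≈ 0.7–0.8, selection ≈ 0.65–0.7 against chance
0.33/0.5), and the movement SNR so that the no-prior decoder reaches
CC ≈ 0.8 — high enough to track the trajectory, low enough that the
regime is not resolved in the first bins, which is precisely the window
where prior knowledge helps.  Under these conditions the three decoders
order none < target < both in CC and success rate, with most of the
success gain coming from the selection prior (the obstacle side is what
the movement likelihood resolves too late).

What the generator does **not** emulate: Poisson/Fano discreteness
beyond rounding, inter-unit noise correlations, non-stationarity and
unit drift across a session, eye movements, failed/discarded trials, the
inter-trial "start = previous target" chaining (conditions are sampled
balanced instead, which is what the decoding mathematics sees), or any
electrode-level signal.  Passing tests therefore demonstrate correctness
and calibration of the pipeline under its own model class, and the
qualitative prior-knowledge effect under realistic SNR — not performance
on real PMd data, where model mismatch (correlated, non-Gaussian noise;
velocity rather than position coding) lowers all absolute numbers.

## Numerical choices

* Covariances are symmetrised after every propagation/update; the
  measurement update uses the Joseph form; innovation solves use
  Cholesky factorisation and raise a clear error if the innovation
  covariance is singular (precluded in practice by the variance floor).
* Variance floors: 1e-6 (observation models, initial state), 1e-4
  (delay-window classifier).
* Mixture weights: log-domain accumulation, max-subtraction, explicit
  renormalisation each bin; weights sum to 1 within 1e-9 by
  construction and by test.
* Least squares throughout is `numpy.linalg.lstsq` (minimum-norm under
  rank deficiency); the dynamics' increment parameterisation makes that
  convention produce the random-walk fallback.
* Ties and degenerate inputs: zero-variance units are kept with floored
  variance (not dropped); zero-variance trajectory coordinates are
  excluded from CC with a warning; a paired t-test on constant
  differences returns p = 1 when the difference is zero and errors
  otherwise.

## Limitations

* The decoder family is linear-Gaussian with a position state; no
  point-process observation models, no closed-loop/online operation, no
  intention-retrained refitting.
* The prior decoder's windows are fixed by the task timeline; no window
  optimisation is attempted.
* Session evaluation assumes a single start position per comparison
  (regimes and priors are defined per start); multi-start sessions are
  analysed start by start.
* The success criterion evaluates the decoded mean path offline; it is
  not a behavioural replay with feedback.
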