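# Methods notes

This note documents the models implemented in `trialhist`, the defaults the
synthetic generator uses, the numerical choices that were genuinely open,
and what validation on synthetic data does and does not establish.

## Task and trial phases

The task model is a self-paced pulsatile evidence-accumulation paradigm:
the subject initiates at a center port, a 1 s train of 15 ms flashes plays
with event onsets at least 25 ms apart, rates are drawn from
{4, 6, 8, 10, 14, 16, 18, 20} events/s around an implicit 12 events/s
boundary, and the high-rate side (right) is rewarded after high-rate
trains. Early withdrawals (leaving the center port before the go cue) end
the trial without a choice.

All frame-indexed analyses run on a common aligned time base of four trial
phases at 30 Hz: early ITI (1.0 s after the previous trial's choice
report; 30 samples), late ITI (1.0 s before to 0.3 s after the previous
trial's outcome end — leaving the reward port after correct choices, end
of punishment/timeout after incorrect ones; 39 samples), stimulus (0.5 s
before to 1.0 s after stimulus onset; 45 samples), action (0.2 s before to
0.3 s after center-port exit; 15 samples); 129 samples per trial in total.
Sample counts use round-half-even on window length × frame rate; windows
are half-open on the frame grid with frame assignment by the nearest frame
at or before the target time. Phases of one trial may overlap in time
(e.g., with short ITIs); each phase is analyzed on its own time base and
may reuse frames. A trial's history label is the previous *completed*
trial's choice × outcome (CL, IL, IR, CR, fixed package-wide ordering); a
withdrawal breaks the chain and leaves the next trial's history undefined.

## Synthetic sessions

The generator defines the study conditions for all tests; its defaults are
fixed once and are not tuned per analysis.

**Behavior.** Choices follow
`p(right) = γ_lo + (1 − γ_lo − γ_hi) σ(β₀ + β₁ x + β⃗_h·h⃗)` with scaled rate
x ∈ [−1, 1] and one-back history indicators h⃗. Defaults: β₀ = 0,
β₁ = 2.5, β⃗_h = (−0.6, −0.1, 0.1, 0.6) — a moderate win-stay pattern of
the size seen in expert perceptual decision-makers — lapses 0.02 each,
15% early withdrawals. Stimulus trains use rejection-free gap allocation:
the slack left after mandatory event durations and minimum gaps is split
among rate+1 segments with exponential proportions, so the minimum-gap
constraint holds by construction for every draw.

**Timing.** ITIs are log-normal (median 3 s, σ_log = 0.6, truncated at
30 s); empirical ITI statistics for this task are not published, so these
are plausible placeholders chosen to exercise ITI-binned decoding up to
~10 s. Two timing constraints are imposed so that the generative neural
model stays exactly linear in the encoding design: the reporting movement
takes 0.35–0.7 s (the action window never spills into the next early ITI)
and re-initiation happens at least 0.85 s after the outcome ends (the late
ITI window never overlaps the next stimulus window).

**Pose and video.** The chest point moves through port way-points
(center at initiation, chosen side port at report) with smoothing, jitter
and mid-ITI wandering — deliberately reproducing the choice ↔ position
collinearity of real freely-moving data. Head angles are smoothed random
walks wrapped to [0°, 360°). Video and motion-energy "SVD" factors are
random linear mixtures of pose-derived signals plus noise with column
variances ordered non-increasingly; with zero noise they lie exactly in
the span of the pose signals.

**Neurons.** Each neuron's latent rate is a linear function of exactly the
feature expansion the encoding design uses: per-context history kernels
over aligned trial time (two-level: one coefficient on ITI timepoints, one
on stimulus/action timepoints; the `stable` regime ties them, the default
`reorganize` regime draws them independently, mirroring an ITI-stable code
that reorganizes at trial start), two-level choice and outcome kernels, a
stimulus-event lag kernel, poke kernels, bin-wise head-angle tuning,
bin-wise place fields, and loadings on the first 10 video factors. Neuron
classes: history (history/choice/outcome kernels only), movement
(pose/video/poke/stimulus only), mixed, and null (all task weights exactly
zero), default 15/15/15/15 of 60 neurons. Emitted traces: an
inferred-spike-rate-like trace (latent + Gaussian noise, σ = 0.5 by
default, floored at 0) and a fluorescence-like trace (latent convolved
with a single-exponential decay, τ = 1 s — a slow-indicator stand-in, not
fitted to data — plus noise, floored at 0). The baseline (3.0) keeps
clipping at zero rare so the generative model stays effectively linear.
An optional `iti_decay_tau` scales the stimulus/action history drive by
exp(−ITI/τ), planting a code that fades with elapsed time.

Passing recovery tests on these sessions shows the estimators are
consistent under the model's own assumptions (linear rate coding, Gaussian
noise, exact bin alignment); it does not establish robustness to
out-of-model features of real data such as nonlinear tuning,
non-stationarity, shared noise, or segmentation artifacts.

## Behavioral estimators

The psychometric likelihood is maximized with L-BFGS-B under box
constraints (α within the rate range ± 5 Hz, β ∈ [10⁻³, 10], lapses
∈ [0, 0.45]) from five deterministic starts; ties break by likelihood,
then smaller total lapse. All-one-class data are flagged degenerate with
parameters at the bounds.

The choice and two-back models balance left/right trials by subsampling
the majority class over 20 rounds with inclusion counts kept within ±1
across rounds, apply 10-fold stratified CV inside each round, and fit at a
fixed L2 penalty of 1 (scikit-learn, C = 1, intercept unpenalized — the
intercept treatment was an open choice). Reported coefficients average
over all fold × round fits; whether to average folds before rounds is
immaterial for the mean. The two-back model has 8 coefficients (intercept,
stimulus, and choice/outcome/interaction at one and two back); interaction
regressors are the products of their main-effect indicators.

## Decoding protocol

Decoders are one-vs-all L2 logistic models per timepoint: 20 subsample
rounds to the minority class count, 8 stratified folds (87.5% / 12.5%),
features standardized by training-fold statistics (SD floored at 10⁻¹²
with a warning-free fallback to 1), penalty selected per fold from decades
10⁻¹⁰…10¹² (23 values). "Best held-out predictions" is measured as the
summed one-vs-all log-likelihood on the test fold: selecting by raw test
accuracy is optimistically biased at small fold sizes (it pushes the
shuffled-label control far above 25%), whereas deviance selection
reproduces the nominal chance level, which is the protocol's own stated
calibration. Class decisions are score argmax with ties broken toward the
lower class index in the fixed (CL, IL, IR, CR) ordering. The solver is a
damped-Newton iteration vectorized over classes and the entire penalty
grid; near-separable problems at the weak end of the grid are capped at 12
iterations (their decision function converges long before their weights),
and the implementation is verified against scikit-learn's logistic
regression at fixed penalties.

Subsample rounds and fold splits are drawn once per decoding run and
shared across timepoints, so cross-temporal generalization reuses each
fold's trained model (including its training-fold scaler) on that fold's
held-out trials at every other timepoint; prediction accuracies are
averaged over folds and rounds, never the coefficients. Per-class accuracy
is recall (diagonal of the row-normalized confusion matrix); this reading
was an open choice and is noted here. Marginal (previous-choice /
previous-outcome) accuracy scores a 4-class prediction as correct when it
agrees on the requested factor only. Trials entering any decoder are
completed and have a defined history label; two-back decoding additionally
requires two completed predecessors. A protocol run refuses label sets
whose minority class is smaller than the fold count.

## Encoding model and variance partition

The design matrix is block-structured per aligned trial row
(trials × 129 timepoints): trial-time indicators act as a time-varying
intercept; choice, outcome and the four history kernels are full-trial
one-hot kernels; stimulus-event kernels span lags 0–0.5 s (16 columns at
30 Hz, lag 0 inclusive); poke kernels span −0.5…+1.0 s (46 columns per
port); head angles use 60 six-degree one-hot bins per angle; chest
position uses 1.28 × 1.28 cm occupancy bins over the arena bounding box
with never-occupied bins dropped (mask recorded) and out-of-arena samples
clamped to edge bins (count recorded); video and motion-energy factors
enter as analog columns, QR-orthogonalized against the stimulus-event
columns. Event kernels shift along the aligned (concatenated-phase) axis;
at phase boundaries this differs from shifting along raw frames, a
deliberate simplification consistent with treating phases as one aligned
trial time.

Ridge fits use 10 folds over *trials* (every fold samples all timepoints),
training-fold standardization of analog columns and of each neuron's
activity, penalty selection per fold and per neuron from decades
10⁻³…10⁵ by held-out R², and held-out predictions reassembled in original
row order; the reported cross-validated R² is computed on those
concatenated predictions (it may be negative). The solver is the
eigendecomposition closed form of ridge, shared across neurons and
penalties within a fold, and matches the analytic solution to 10⁻⁶.

Variance partitioning shuffles whole trials: the targeted variable's
columns of trial i are replaced by those of a random other trial,
preserving within-trial temporal structure so the shuffled model is a fair
null. The trial-time block stays intact in every reduced model (it is the
time-varying intercept). maximal(v) = R²(only v) − R²(time-only);
unique(v) = R²(full) − R²(v removed). Because held-out R² of reduced
models can be slightly negative, maximal(v) ≤ R²(single) is only
guaranteed when the time-only R² is non-negative, and no ordering between
unique and maximal is asserted (suppression can invert it). Time-resolved
R² is computed per aligned timepoint from the reordered held-out
predictions; timepoints with zero across-trial variance are reported
absent, and the mean of per-timepoint R² need not match the full-trial R².

## Geometry

For a variable's weights (neurons × conditions·timepoints,
condition-major, columns mean-centered across neurons), dimensionality is
the smallest number of principal components reaching 90% cumulative
variance with neurons as observations. Trajectory shapes are the top-k
component loadings scaled by component standard deviations, one point per
(condition, timepoint). Procrustes alignment optimizes translation,
positive uniform scale and an orthogonal rotation (reflections allowed —
the standard unrestricted choice); the dissimilarity is the residual
normalized by the centered reference's total variance,
1 − (Σσ)² / (‖X₁‖²‖X₂‖²) ∈ [0, 1], i.e., a normalized squared-disparity
convention (the square root is not taken). Cross-session comparisons use
the maximal per-variable dimensionality across sessions for all sessions;
each unordered session pair is compared once with the earlier-listed
session as reference (the measure is asymmetric in target/reference roles,
which is recorded).

## Problem sizes and determinism

Default test and acceptance problem sizes — 150–300 trials, 6–60 neurons,
8–20 video components, decoding at timepoint subsets, encoding partitions
restricted to the early-ITI phase and a variable subset — were chosen so
the full validation cycle runs on a single CPU in minutes while leaving
the protocols themselves (20 rounds, 8 or 10 folds, full penalty grids) at
their stated values. The chance calibration averages 200 independent
shuffled runs at one early-ITI timepoint. All randomness flows from seeded
`numpy` generators: sessions split one root seed per component
(behavior, pose, video, ground truth, neurons), and every analysis
function takes an explicit seed; identical seeds give identical results.

## Known limitations

- The generator produces linear rate codes with independent Gaussian
  noise; no spiking statistics, shared variability, or
  fluorescence-to-spike inference mismatch.
- Pose is way-point interpolation, not biomechanics; video factors are
  pose mixtures, so "uninstructed movements" beyond pose are absent.
- Statistical inference across sessions/subjects (mixed-effects testing,
  multiple-comparison correction) is intentionally out of scope; shuffle
  distributions are reported for the user's own inference.
- Session filtering criteria (wait > 1 s, ≥ 2 boundary-symmetric rate
  pairs, ≥ 100 completed trials, ≤ 55% withdrawals) operate on summary
  tables; the generator does not emulate under-trained subjects.
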