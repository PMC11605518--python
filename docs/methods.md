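# Methods

This note documents the models, the synthetic data the package is tested
on, and the numerical choices, in the package's own words.

## Problem

A regression-based neuroprosthesis maps multi-channel intramuscular EMG
(iEMG) to simultaneous proportional positions of 12 hand/wrist degrees of
freedom (DOFs), each normalized to [-1, 1]. Because EMG statistics drift
from day to day, decoders trained on a single calibration session decay
over time and are traditionally retrained daily from scratch. The package
implements and evaluates the alternative: *dataset aggregation*, training
on the concatenation of the most recent K calibration sessions
(K = 1, 5, 10) instead of only the newest one.

## Feature chain (`preprocess`)

Raw EMG (contacts x samples, 1 kHz) is filtered causally — sixth-order
15 Hz high-pass and second-order 375 Hz low-pass Butterworth, plus 60/120/
180 Hz notches (IIR biquads, 2 Hz bandwidth; the notch Q is an
implementation choice) — then expanded with all pairwise differential
signals (n + C(n, 2) channels; 528 for 32 contacts, 210 for 20), and
reduced to mean-absolute-value (MAV) features over a *trailing* 300 ms
window sampled at 30 Hz. Trailing (causal) windows are used because the
identical chain must be realizable in real time; the window's ~150 ms
group delay is absorbed by the lag alignment below.

The user's visuomotor reaction time is removed by cross-correlating the
channel-mean MAV with the DOF-mean |kinematics| over nonnegative lags up
to 1 s and *delaying* the kinematics by the argmax (one global lag per
session, rest padding). Delay — not advance — is the physically meaningful
direction: muscles react after the displayed target moves.

## Decoders

**MKF.** A Kalman filter whose state is the 12-DOF position. A (state
transition) and H (observation) are least-squares fits; W and Q are the
residual covariances. Features are baseline-subtracted (each session's own
rest-frame mean) and reduced to 48 channels by stepwise Gram-Schmidt
forward selection: at each step every remaining channel is residualized
against the selected span and scored by the sum over DOFs of squared
correlation with the kinematic traces (the forward orthogonal-least-squares
criterion generalized to 12 targets; ties break to the lowest index,
residuals below 1e-10 of the original norm are treated as rank-deficient).
The decoder output is passed through a dead zone (|x| <= 0.2 -> 0, values
beyond pass through unrescaled, leaving a discontinuity at +/-0.2) and
clamped to [-1, 1]. The recursion starts at rest with covariance 10 I; for
a time-invariant model the gain converges, and once successive gains agree
to 1e-9 the steady-state gain is reused (verified lossless to 1e-6).

**CNN.** Input is the N x 10 image of all N features at the current and
nine previous frames (first nine frames edge-replicated). One
convolutional layer (ten 1 x 5 kernels, time axis only) yields an
N x 6 x 10 map, ReLU, then two fully connected layers of 2N units with
ReLU and a linear 12-output regression head. Training is SGD with momentum
0.9 at learning rate 1e-5, MSE loss, on a random 60 % of movement trials
(stratified per movement), validated on the held-out 40 %; training stops
when validation loss has not decreased for 20 consecutive epoch-end checks
and the best-validation weights are returned. Features are z-scored with
training-set statistics before the network (`standardize=False` reproduces
the literal raw-MAV pipeline, which trains impractically slowly at this
learning rate). The output layer is initialized small (std 0.01) so
initial predictions sit at the rest posture — the marginal mode of the
targets — rather than random O(1) values. Mini-batches of 32 (8 in the
large simulation study): at a pinned learning rate the number of SGD steps
is the binding resource, and smaller batches buy 2-4x more steps per unit
CPU at equal data exposure. An optional `visit_budget` caps epochs x
training windows so that every aggregation size receives the same
optimizer work in the comparison study.

## Synthetic multi-session data (`synthgen`)

No public data exist for this paradigm, so the generator emulates the
calibration recordings' structure:

* **Protocol.** Blocked mimicry trials: the active DOF ramps linearly to
  direction x amplitude over 3 s, holds 1 s, returns over 3 s (7 s = 210
  frames at 30 Hz), with 2 s inter-trial rest; all other DOFs exactly 0.
  The default offline protocol has 8 single-DOF movements x 6 trials.
* **Subject.** A nonnegative mixing matrix maps the 24 rectified
  flexion/extension drives to contact envelopes: each drive targets two
  dedicated contacts plus a diffuse background (neighbouring-muscle
  bleed-through), with per-contact rest baselines and white measurement
  noise. Mean reaction lag 200 ms.
* **EMG.** envelope x unit-variance 15-375 Hz Gaussian carrier + white
  noise at 1 kHz. A feature-level shortcut returns the closed-form
  expected MAV (E|N(0, s^2)| = s sqrt(2/pi); differential pairs combine
  independent carriers in quadrature) plus Gaussian jitter, and is used
  for large studies and fast tests; its agreement with the full
  filter+MAV chain is itself tested.
* **Imperfect mimicry.** Each trial's performed kinematics are the
  displayed target scaled by a random effort factor (sd 0.12) and shifted
  by per-trial lag jitter (sd 30 ms); labels remain the displayed target.
  This trial-level label noise is what makes a single session a *noisy
  sample* of the subject — without it, aggregation would have nothing to
  average over.
* **Drift.** Two components share three rate knobs (all per day):
  a cumulative seeded random walk — per-contact log-gain steps (sd 0.06),
  Givens rotations of random contact-space planes (sd 0.05 rad), baseline
  steps (sd 0.005), each modulated by a fixed per-contact susceptibility —
  plus a *session-specific reversible state* (impedance, posture, user
  state of the day) drawn fresh per day with `session_scale` = 3 times the
  per-day steps. The reversible state is why day-to-day feature clusters
  scatter instead of marching in order, and why no single past session is
  a privileged stand-in for a future one; the walk is why performance
  decays with calendar time. Zero rates silence both components, making
  sessions statistically identical across days (tested). Defaults were
  calibrated once so that a movement's feature-cluster centroid moves by
  ~1.5-2x the within-session spread over two months — the qualitative
  between-day separation the analysis presumes — and frozen.

What the generator does **not** model: motor-unit physiology and MUAP
shapes, electrode geometry, within-session fatigue trends, human learning
across sessions, and online (closed-loop) corrections. Passing results on
this data show that the pipeline mechanics and the aggregation effects are
implemented correctly under the stated drift model, not that the same
effect sizes would be observed in any particular participant.

## Study designs (`experiment`)

The offline study mirrors the aggregated-training design: per synthetic
subject (one seed = one subject), ten calibration sessions on days
0, 3, ..., 27 and two held-out test sessions on days 33 and 89 (the real
datasets span roughly three months to ten months; a two-month test lever
arm keeps the cumulative drift identifiable over the session-state noise
with two test sessions). Both decoders are trained on the last 1, 5 and
10 sessions (6 conditions) and scored per test trial:

* **Intended movement RMSE** — error on the trial's active DOF over the
  annotated span.
* **Unintended movement RMSE** — each resting DOF's RMSE against zero,
  averaged over the 11 resting DOFs (cross-talk).
* **Robustness slope** — per DOF, the least-squares slope of
  whole-session RMSE (all frames, so cross-talk dominates) versus days
  since the most recent aggregated session; summarized by median and IQR
  across DOFs and subjects.

The target-touching task (TTT) is replayed offline: 12 movements (both
directions of 6 DOFs) x 5 trials at 50 % and 5 at 100 % amplitude, 5 s
trials (1 s approach + 4 s hold), 2 s rest; scored by windowed RMSE
(per-frame error max(0, |e| - 0.15) — inside the +/-0.15 feedback window
counts as zero), percent time with *all* DOFs in their windows, longest
continuous hold, and log mean absolute jerk (third-order central
difference x framerate^3, active DOFs only; a constant trace returns -inf
with a warning). The +/-15 % window is an absolute +/-0.15 in normalized
units, since rest targets at 0 make percent-of-target undefined.

Group contrasts use Kruskal-Wallis; when significant, pairwise Dunn/Nemenyi
rank statistics with studentized-range (Tukey-style) correction, which is
approximate under heavy ties.

## Numerical and scale choices

* Study scale: N = 66 features (11 contacts + 55 pairs), 8 movements x 6
  trials x 12 sessions x 10 subjects; CNN trained with a 144k-visit budget
  per condition at batch 8 (18k SGD steps), window stride 4, validation
  loss estimated on up to 800 held-out windows per check. These sizes are
  the package's simulation defaults; they keep a full 60-condition study
  to roughly twenty CPU-minutes while leaving every qualitative contrast
  intact.
* Gram-Schmidt selection inside the study uses every 3rd frame (the
  correlation ranking is insensitive to this; the fitted models use all
  frames).
* Filters reject recordings shorter than ~3 transient lengths of the
  slowest section. MAV uses an exact cumulative-sum implementation
  (matches a naive windowed mean to 1e-12).
* Kalman fitting uses `lstsq` (rank-safe) rather than normal equations; Q
  gets a 1e-9 diagonal guard against degenerate training data.

## Known limitations

* The session-state/walk decomposition of drift is phenomenological; only
  its qualitative consequences (cluster scatter, slow decay, benefit of
  aggregation) are calibrated, not any quantitative drift statistics.
* The MKF's post-threshold discontinuity follows the stated zeroing rule;
  whether the original modified filter rescales beyond the dead zone is
  left open by its description.
* The simulated TTT user is stationary within a session; human learning
  across sessions (a large effect online) is deliberately not modelled.
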