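"""Synthetic multi-session EMG/kinematics generator.

The generator emulates the structure of mimicry-calibration recordings for
an implanted-EMG neuroprosthesis: a participant copies prerecorded
single-DOF trapezoidal movements (3 s rise, 1 s hold, 3 s return) while
multi-channel EMG is recorded.  Muscle drive is modelled as a nonnegative
mixing of rectified flexion/extension kinematics into contact envelopes;
each contact carries an amplitude-modulated band-limited Gaussian carrier
plus white measurement noise, and the user's visuomotor reaction time
delays the EMG relative to the displayed kinematics.

Day-to-day signal nonstationarity — the reason decoders degrade between
calibrations — is modelled as a seeded random walk applied to the subject:
per-contact multiplicative log-gain steps, small Givens rotations of the
contact-space mixing, and an additive rest-baseline walk.  Contacts differ
in how strongly they drift (a per-contact susceptibility drawn once per
drift process), which mirrors the empirical observation that some implanted
contacts are stable for months while others wander.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import N_DOF, EmgRecording, FeatureMatrix, KinematicTrace, Session, TrialAnnotation

#: E|X| / std(X) for a zero-mean Gaussian: sqrt(2 / pi).
GAUSS_RECTIFIED_MEAN = math.sqrt(2.0 / math.pi)

#: Number of rectified drive signals: 12 DOFs x {flexion, extension}.
N_DRIVES = 2 * N_DOF


@dataclass(frozen=True)
class MovementSpec:
    """A single calibration movement (one or more DOFs, one direction)."""

    movement_id: int
    active_dofs: tuple[int, ...]
    direction: int = 1
    target_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 (flexion) or -1 (extension)")
        if not 0.0 < self.target_amplitude <= 1.0:
            raise ValueError("target amplitude must lie in (0, 1]")
        if any(d < 0 or d >= N_DOF for d in self.active_dofs):
            raise ValueError("active DOF indices must lie in 0..11")


@dataclass
class MovementProtocol:
    """Blocked mimicry protocol: each movement repeated before the next."""

    movements: list[MovementSpec]
    trials_per_movement: int = 6
    rise_s: float = 3.0
    hold_s: float = 1.0
    return_s: float = 3.0
    inter_trial_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.movements:
            raise ValueError("protocol needs at least one movement")
        if self.trials_per_movement < 1:
            raise ValueError("trials_per_movement must be positive")
        if self.rise_s + self.hold_s + self.return_s <= 0:
            raise ValueError("trial duration must be positive")

    @property
    def trial_s(self) -> float:
        return self.rise_s + self.hold_s + self.return_s


def default_protocol(
    n_movements: int = 8,
    trials_per_movement: int = 6,
    amplitude: float = 1.0,
    **kwargs,
) -> MovementProtocol:
    """Single-DOF movements over the first ``n_movements`` DOFs.

    Directions alternate flexion/extension so both rectified drives are
    exercised across the protocol.
    """
    movements = [
        MovementSpec(
            movement_id=m,
            active_dofs=(m % N_DOF,),
            direction=1 if m % 2 == 0 else -1,
            target_amplitude=amplitude,
        )
        for m in range(n_movements)
    ]
    return MovementProtocol(movements=movements, trials_per_movement=trials_per_movement, **kwargs)


@dataclass
class SubjectModel:
    """Contact-to-muscle structure of one synthetic participant.

    ``mixing`` maps the 24 rectified DOF-direction drives (columns ordered
    flexion then extension per DOF) to contact envelope amplitude.
    """

    n_contacts: int
    mixing: np.ndarray
    rest_baseline: np.ndarray
    noise_sd: np.ndarray
    reaction_lag_s: float = 0.2

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.rest_baseline = np.asarray(self.rest_baseline, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.mixing.shape != (self.n_contacts, N_DRIVES):
            raise ValueError(f"mixing must be ({self.n_contacts}, {N_DRIVES})")
        if np.any(self.mixing < 0):
            raise ValueError("mixing entries must be nonnegative")
        if self.reaction_lag_s < 0:
            raise ValueError("reaction lag must be nonnegative")

    def copy(self) -> "SubjectModel":
        return copy.deepcopy(self)


def default_subject(n_contacts: int = 32, seed: int = 0, reaction_lag_s: float = 0.2) -> SubjectModel:
    """Random but structured subject: each drive targets a few contacts.

    Every DOF-direction drives two dedicated contacts plus a weak diffuse
    background, so kinematics are recoverable but channels overlap the way
    neighbouring muscles do.
    """
    rng = np.random.default_rng(seed)
    # Diffuse background cross-contamination plus two dedicated contacts per
    # drive: neighbouring muscles bleed into the same leads.
    mixing = rng.uniform(0.0, 0.08, size=(n_contacts, N_DRIVES))
    for drive in range(N_DRIVES):
        contacts = rng.choice(n_contacts, size=2, replace=False)
        mixing[contacts, drive] += rng.uniform(0.35, 1.0, size=2)
    rest_baseline = rng.uniform(0.05, 0.15, size=n_contacts)
    noise_sd = rng.uniform(0.02, 0.04, size=n_contacts)
    return SubjectModel(
        n_contacts=n_contacts,
        mixing=mixing,
        rest_baseline=rest_baseline,
        noise_sd=noise_sd,
        reaction_lag_s=reaction_lag_s,
    )


@dataclass
class DriftModel:
    """Day-indexed nonstationarity process.

    Two components share the same three rate knobs:

    * a *cumulative* seeded random walk (per-contact multiplicative
      log-gain steps, small Givens rotations of random 2-D contact
      subspaces of the mixing matrix, additive rest-baseline steps), which
      makes sessions decorrelate slowly with calendar distance; and
    * a *session-specific* reversible state (electrode impedance, posture,
      user state of the day), drawn fresh per day with std
      ``session_scale`` times the corresponding per-day rate.  This is why
      day-to-day feature clusters scatter rather than marching in order,
      and why no single past session is a privileged stand-in for a
      future one.

    rotation_rate
        Std of the per-day rotation angle (radians/day).
    gain_sd_per_day
        Std of the per-day step of each contact's log-gain.
    baseline_sd_per_day
        Std of the per-day additive step of each contact's rest level.
    session_scale
        Ratio of the day-specific state's std to the per-day walk step.
        Rates of zero therefore silence both components.
    """

    rotation_rate: float = 0.05
    gain_sd_per_day: float = 0.06
    baseline_sd_per_day: float = 0.005
    session_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rotation_rate, self.gain_sd_per_day, self.baseline_sd_per_day) < 0:
            raise ValueError("drift rates must be nonnegative")
        if self.session_scale < 0:
            raise ValueError("session_scale must be nonnegative")


def apply_day_drift(subject: SubjectModel, drift: DriftModel, day_index: int) -> SubjectModel:
    """Subject as it would appear ``day_index`` days after day 0.

    Deterministic given (drift.seed, day_index): the walk is replayed from
    day 0 on every call, so the same day always yields a bit-identical
    subject and rates of zero leave the subject unchanged.
    """
    if day_index < 0:
        raise ValueError("day_index must be nonnegative")
    out = subject.copy()
    if day_index == 0:
        return out
    n = subject.n_contacts
    rng = np.random.default_rng(np.random.SeedSequence([int(drift.seed) & 0x7FFFFFFF, 0xD21F]))
    # Per-contact drift susceptibility, fixed for the whole walk.
    susceptibility = rng.uniform(0.2, 1.8, size=n)
    log_gain = np.zeros(n)
    mixing = out.mixing.copy()
    baseline = out.rest_baseline.copy()
    n_rot = max(1, n // 4)
    def rotate(angle_sd: float, gen: np.random.Generator) -> None:
        for _ in range(n_rot):
            i, j = gen.choice(n, size=2, replace=False)
            theta = gen.normal(0.0, angle_sd) * 0.5 * (susceptibility[i] + susceptibility[j])
            c, s = math.cos(theta), math.sin(theta)
            ri, rj = mixing[i].copy(), mixing[j].copy()
            mixing[i] = c * ri - s * rj
            mixing[j] = s * ri + c * rj

    # Cumulative random walk, replayed day by day.
    for _ in range(day_index):
        log_gain += rng.normal(0.0, drift.gain_sd_per_day, size=n) * susceptibility
        rotate(drift.rotation_rate, rng)
        baseline += rng.normal(0.0, drift.baseline_sd_per_day, size=n) * susceptibility

    # Day-specific reversible state, independent across days.
    day_rng = np.random.default_rng(
        np.random.SeedSequence([int(drift.seed) & 0x7FFFFFFF, int(day_index), 0xDA7])
    )
    scale = drift.session_scale
    log_gain += day_rng.normal(0.0, scale * drift.gain_sd_per_day, size=n) * susceptibility
    rotate(scale * drift.rotation_rate, day_rng)
    baseline += day_rng.normal(0.0, scale * drift.baseline_sd_per_day, size=n) * susceptibility

    out.mixing = np.clip(mixing * np.exp(log_gain)[:, None], 0.0, None)
    out.rest_baseline = np.clip(baseline, 0.005, None)
    return out


def make_kinematic_trace(
    protocol: MovementProtocol, frame_rate: float = 30.0
) -> tuple[KinematicTrace, list[TrialAnnotation]]:
    """Trapezoidal single/multi-DOF target kinematics plus trial spans.

    Each trial ramps the active DOF(s) linearly from rest to
    ``direction * amplitude`` over ``rise_s``, holds, and ramps back; all
    other DOFs stay exactly zero.  Trials are separated (and preceded) by
    ``inter_trial_s`` of rest.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rise_f = int(round(protocol.rise_s * frame_rate))
    hold_f = int(round(protocol.hold_s * frame_rate))
    return_f = int(round(protocol.return_s * frame_rate))
    gap_f = int(round(protocol.inter_trial_s * frame_rate))
    trial_f = rise_f + hold_f + return_f
    if trial_f <= 0:
        raise ValueError("trial must span at least one frame")

    n_trials = len(protocol.movements) * protocol.trials_per_movement
    total = gap_f + n_trials * (trial_f + gap_f)
    values = np.zeros((N_DOF, total))
    annotations: list[TrialAnnotation] = []

    profile = np.concatenate(
        [
            np.arange(1, rise_f + 1) / max(rise_f, 1),
            np.ones(hold_f),
            1.0 - np.arange(1, return_f + 1) / max(return_f, 1),
        ]
    )
    cursor = gap_f
    for move in protocol.movements:
        for _ in range(protocol.trials_per_movement):
            peak = move.direction * move.target_amplitude
            for dof in move.active_dofs:
                values[dof, cursor : cursor + trial_f] = peak * profile
            annotations.append(
                TrialAnnotation(
                    movement_id=move.movement_id,
                    active_dofs=move.active_dofs,
                    direction=move.direction,
                    target_amplitude=move.target_amplitude,
                    frame_start=cursor,
                    frame_end=cursor + trial_f,
                )
            )
            cursor += trial_f + gap_f
    return KinematicTrace(values=values, frame_rate=frame_rate), annotations


def performed_kinematics(
    kin: KinematicTrace,
    annotations: list[TrialAnnotation],
    rng: np.random.Generator,
    effort_sd: float = 0.12,
    lag_jitter_sd: float = 0.03,
    frame_rate: float | None = None,
) -> KinematicTrace:
    """What the user's muscles actually did, as opposed to the displayed target.

    Mimicry is imperfect: each trial is performed with a random effort scale
    (amplitude over/undershoot) and a per-trial timing jitter around the
    mean reaction lag.  Decoders are trained against the *displayed*
    kinematics, so these deviations act as label noise — the reason a
    single calibration session is a noisy sample of the user.
    """
    fr = frame_rate or kin.frame_rate
    out = np.zeros_like(kin.values)
    rest_mask = np.ones(kin.n_frames, dtype=bool)
    for a in annotations:
        rest_mask[a.frame_start : a.frame_end] = False
    for a in annotations:
        effort = float(np.clip(rng.normal(1.0, effort_sd), 0.6, 1.4))
        jitter = int(round(rng.normal(0.0, lag_jitter_sd) * fr))
        seg = kin.values[:, a.frame_start : a.frame_end] * effort
        start = a.frame_start + jitter
        lo, hi = max(start, 0), min(start + seg.shape[1], kin.n_frames)
        out[:, lo:hi] = seg[:, lo - start : hi - start]
    out = np.clip(out, -1.0, 1.0)
    return KinematicTrace(values=out, frame_rate=kin.frame_rate)


def _drive_matrix(kin_values: np.ndarray) -> np.ndarray:
    """Rectified flexion/extension drives, shape (24, n)."""
    drives = np.zeros((N_DRIVES, kin_values.shape[1]))
    drives[0::2] = np.clip(kin_values, 0.0, None)
    drives[1::2] = np.clip(-kin_values, 0.0, None)
    return drives


def _delayed(kin: KinematicTrace, lag_s: float, times: np.ndarray) -> np.ndarray:
    """Kinematics sampled at ``times`` (s), delayed by ``lag_s``."""
    frame_times = np.arange(kin.n_frames) / kin.frame_rate
    query = times - lag_s
    out = np.empty((N_DOF, times.size))
    for d in range(N_DOF):
        out[d] = np.interp(query, frame_times, kin.values[d], left=kin.values[d, 0])
    return out


def synthesize_emg(
    kin: KinematicTrace,
    subject: SubjectModel,
    seed: int,
    fs: float = 1000.0,
    carrier_band: tuple[float, float] = (15.0, 375.0),
) -> EmgRecording:
    """Amplitude-modulated band-limited EMG for a kinematic trace.

    Per contact ``c`` the envelope is
    ``rest_baseline[c] + sum_d mixing[c, d] * drive_d(t - reaction_lag)``;
    the output is ``envelope * carrier + white noise`` with a unit-variance
    15-375 Hz Gaussian carrier.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(kin.n_frames * fs / kin.frame_rate))
    times = np.arange(n_samples) / fs
    kin_delayed = _delayed(kin, subject.reaction_lag_s, times)
    envelope = subject.rest_baseline[:, None] + subject.mixing @ _drive_matrix(kin_delayed)
    assert np.all(envelope >= 0), "envelope must be nonnegative by construction"

    sos = signal.butter(4, carrier_band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal((subject.n_contacts, n_samples)), axis=1)
    sd = carrier.std(axis=1, keepdims=True)
    carrier /= np.where(sd > 0, sd, 1.0)

    noise = rng.standard_normal((subject.n_contacts, n_samples)) * subject.noise_sd[:, None]
    return EmgRecording(data=envelope * carrier + noise, fs=fs)


def synthesize_features(
    kin: KinematicTrace,
    subject: SubjectModel,
    seed: int,
    include_pairs: bool = True,
    jitter_sd: float = 0.005,
) -> FeatureMatrix:
    """Feature-level shortcut: expected MAV of the full EMG chain.

    For the carrier model, the expected MAV of contact ``i`` is
    ``sqrt(env_i^2 + noise_i^2) * sqrt(2/pi)`` and of the differential pair
    ``(i, j)`` (independent carriers)
    ``sqrt(env_i^2 + env_j^2 + noise_i^2 + noise_j^2) * sqrt(2/pi)``.
    Frame-level estimation noise is approximated by additive Gaussian
    jitter.  Orders of magnitude faster than synthesizing 1 kHz EMG; used
    for large simulation studies and quick tests.
    """
    rng = np.random.default_rng(seed)
    fr = kin.frame_rate
    lag_f = int(round(subject.reaction_lag_s * fr))
    shifted = np.zeros_like(kin.values)
    if lag_f == 0:
        shifted[:] = kin.values
    else:
        shifted[:, lag_f:] = kin.values[:, : kin.n_frames - lag_f]
    envelope = subject.rest_baseline[:, None] + subject.mixing @ _drive_matrix(shifted)
    var = envelope**2 + (subject.noise_sd**2)[:, None]

    labels = [f"c{i:02d}" for i in range(subject.n_contacts)]
    blocks = [var]
    if include_pairs:
        i_idx, j_idx = np.triu_indices(subject.n_contacts, k=1)
        blocks.append(var[i_idx] + var[j_idx])
        labels += [f"c{i:02d}-c{j:02d}" for i, j in zip(i_idx, j_idx)]
    mav = np.sqrt(np.concatenate(blocks, axis=0)) * GAUSS_RECTIFIED_MEAN
    mav = np.clip(mav + rng.normal(0.0, jitter_sd, size=mav.shape), 0.0, None)
    return FeatureMatrix(values=mav, frame_rate=fr, channel_labels=labels)


def generate_study(
    subject: SubjectModel,
    protocol: MovementProtocol,
    drift: DriftModel,
    day_indices: list[int],
    mode: str = "emg",
    frame_rate: float = 30.0,
    effort_sd: float = 0.12,
    lag_jitter_sd: float = 0.03,
) -> list[Session]:
    """One session per day index, using the drifted subject for that day.

    The EMG is driven by the *performed* kinematics (imperfect mimicry via
    :func:`performed_kinematics`) while the stored labels are the displayed
    target kinematics, as in a real calibration recording.  ``mode='emg'``
    stores raw 1 kHz EMG (the full preprocessing chain is then exercised
    downstream); ``mode='features'`` stores expected-MAV features directly
    via :func:`synthesize_features`.
    """
    if list(day_indices) != sorted(day_indices):
        raise ValueError("day_indices must be nondecreasing")
    if mode not in ("emg", "features"):
        raise ValueError("mode must be 'emg' or 'features'")
    sessions: list[Session] = []
    for day in day_indices:
        day_subject = apply_day_drift(subject, drift, day)
        kin, annotations = make_kinematic_trace(protocol, frame_rate=frame_rate)
        seed_pair = np.random.SeedSequence(
            [int(drift.seed) & 0x7FFFFFFF, int(day), 0x5E55]
        ).generate_state(2)
        sub_seed = int(seed_pair[0] % (2**31))
        performed = performed_kinematics(
            kin,
            annotations,
            np.random.default_rng(int(seed_pair[1] % (2**31))),
            effort_sd=effort_sd,
            lag_jitter_sd=lag_jitter_sd,
        )
        kwargs: dict = {"kinematics": kin, "annotations": annotations, "day_index": int(day)}
        if mode == "emg":
            kwargs["emg"] = synthesize_emg(performed, day_subject, seed=sub_seed)
        else:
            kwargs["features"] = synthesize_features(performed, day_subject, seed=sub_seed)
        sessions.append(Session(**kwargs))
    return sessions
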