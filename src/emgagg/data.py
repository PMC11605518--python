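"""Core data containers shared across the decoding pipeline.

Conventions used throughout the package:

* EMG is stored contacts-by-samples at ``fs`` Hz (default 1 kHz).
* Kinematics are 12 degree-of-freedom (DOF) positions in ``[-1, 1]`` at the
  feature frame rate (default 30 Hz).  ``+1`` is maximum
  flexion/abduction/pronation, ``-1`` maximum extension/adduction/supination,
  ``0`` the hand at rest.
* Features are nonnegative mean-absolute-value (MAV) amplitudes,
  channels-by-frames, single-ended contacts first and then all ordered
  differential pairs ``(i, j)`` with ``i < j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Number of kinematic degrees of freedom tracked by the virtual hand.
N_DOF = 12


@dataclass
class EmgRecording:
    """Raw multi-channel EMG, ``data`` shaped (n_contacts, n_samples)."""

    data: np.ndarray
    fs: float = 1000.0
    contact_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.contact_ids is None:
            self.contact_ids = [f"c{i:02d}" for i in range(self.data.shape[0])]
        if len(self.contact_ids) != self.data.shape[0]:
            raise ValueError("contact_ids length does not match channel count")

    @property
    def n_contacts(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class KinematicTrace:
    """12-DOF position trace in [-1, 1], ``values`` shaped (12, n_frames)."""

    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != N_DOF:
            raise ValueError(f"kinematics must have {N_DOF} DOF rows")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.values.size and np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("kinematic values must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TrialAnnotation:
    """One movement trial: active DOF set and its frame span [start, end)."""

    movement_id: int
    active_dofs: tuple[int, ...]
    direction: int
    target_amplitude: float
    frame_start: int
    frame_end: int

    def __post_init__(self) -> None:
        if not self.active_dofs:
            raise ValueError("a trial must have at least one active DOF")
        if any(d < 0 or d >= N_DOF for d in self.active_dofs):
            raise ValueError("active DOF indices must lie in 0..11")
        if self.frame_end <= self.frame_start:
            raise ValueError("annotation span is empty")

    @property
    def n_frames(self) -> int:
        return self.frame_end - self.frame_start

    def span(self) -> slice:
        return slice(self.frame_start, self.frame_end)

    def shifted(self, lag_frames: int, n_frames: int) -> "TrialAnnotation":
        """Span after the kinematics were delayed by ``lag_frames``."""
        start = min(self.frame_start + lag_frames, n_frames - 1)
        end = min(self.frame_end + lag_frames, n_frames)
        return replace(self, frame_start=start, frame_end=max(end, start + 1))


@dataclass
class FeatureMatrix:
    """MAV feature channels by frames at ``frame_rate`` Hz.

    Values are nonnegative for raw MAV features; baseline-subtracted
    features (Kalman path) may legitimately go negative, so nonnegativity
    is not enforced here.
    """

    values: np.ndarray
    frame_rate: float = 30.0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.channel_labels is not None and len(self.channel_labels) != self.values.shape[0]:
            raise ValueError("channel_labels length does not match feature count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Session:
    """One recording session: EMG and/or features, kinematics, annotations."""

    kinematics: KinematicTrace
    annotations: list[TrialAnnotation] = field(default_factory=list)
    day_index: int = 0
    emg: EmgRecording | None = None
    features: FeatureMatrix | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.emg is None and self.features is None:
            raise ValueError("a session needs raw EMG or a feature matrix")
        n_frames = self.kinematics.n_frames
        spans = sorted((a.frame_start, a.frame_end) for a in self.annotations)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("annotation spans overlap")
        if spans and (spans[0][0] < 0 or spans[-1][1] > n_frames):
            raise ValueError("annotation span outside kinematic range")
        if self.emg is not None:
            expected = self.emg.n_samples * self.kinematics.frame_rate / self.emg.fs
            if abs(expected - n_frames) > 1.0 + 1e-9:
                raise ValueError(
                    "EMG duration and kinematic frame count disagree by more than one frame"
                )
        if self.features is not None and self.features.n_frames != n_frames:
            raise ValueError("feature frames and kinematic frames differ")

    @property
    def n_frames(self) -> int:
        return self.kinematics.n_frames


@dataclass
class TrainingSet:
    """Frame-aligned training material, possibly aggregated over sessions."""

    features: FeatureMatrix
    kinematics: KinematicTrace
    annotations: list[TrialAnnotation]
    day_indices: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.features.n_frames


def clamp_unit(values: np.ndarray) -> np.ndarray:
    """Clip decoder output to the valid kinematic range [-1, 1]."""
    return np.clip(values, -1.0, 1.0)


@dataclass
class DecodedTrace:
    """Decoder output: 12-DOF estimates clamped to [-1, 1]."""

    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != N_DOF:
            raise ValueError(f"decoded trace must have {N_DOF} rows")
        if self.values.size and np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("decoded values must be clamped to [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]
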