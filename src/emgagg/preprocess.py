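"""Raw EMG to decoder features: filtering, differential pairs, MAV, alignment.

The chain mirrors a real-time implanted-EMG rig: causal Butterworth
band-pass (15 Hz sixth-order high-pass, 375 Hz second-order low-pass) with
60/120/180 Hz notches, differential signals for all contact pairs, and the
mean absolute value (MAV) over a trailing 300 ms window sampled at 30 Hz.
All filtering and windowing is forward-only so the identical code path
could run online.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .data import EmgRecording, FeatureMatrix, KinematicTrace, TrialAnnotation


@dataclass
class FilterSpec:
    """Band-pass plus notch filter bank for raw EMG at ``fs`` Hz."""

    hp_cutoff: float = 15.0
    hp_order: int = 6
    lp_cutoff: float = 375.0
    lp_order: int = 2
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    notch_bandwidth: float = 2.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff < self.fs / 2:
            raise ValueError("need 0 < hp_cutoff < lp_cutoff < fs/2")

    def sos(self) -> np.ndarray:
        """Composed second-order sections: high-pass, low-pass, notches."""
        sections = [
            signal.butter(self.hp_order, self.hp_cutoff, btype="highpass", fs=self.fs, output="sos"),
            signal.butter(self.lp_order, self.lp_cutoff, btype="lowpass", fs=self.fs, output="sos"),
        ]
        for f0 in self.notch_freqs:
            b, a = signal.iirnotch(f0, f0 / self.notch_bandwidth, fs=self.fs)
            sections.append(signal.tf2sos(b, a))
        return np.vstack(sections)

    def min_samples(self) -> int:
        # ~3 transient lengths of the slowest (high-pass) section.
        return int(3 * self.hp_order * self.fs / self.hp_cutoff)


def bandpass_notch(emg: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Causal band-pass + notch filtering, per channel."""
    spec = spec or FilterSpec(fs=emg.fs)
    if abs(spec.fs - emg.fs) > 1e-9:
        raise ValueError("filter spec sampling rate does not match recording")
    if emg.n_samples < spec.min_samples():
        raise ValueError(
            f"recording too short to filter: {emg.n_samples} samples "
            f"< {spec.min_samples()} (transient-dominated)"
        )
    filtered = signal.sosfilt(spec.sos(), emg.data, axis=1)
    return EmgRecording(data=filtered, fs=emg.fs, contact_ids=list(emg.contact_ids))


def pair_labels(ids: list[str]) -> list[str]:
    """Single-ended labels followed by lexicographic pair labels."""
    return list(ids) + [f"{a}-{b}" for a, b in combinations(ids, 2)]


def differential_pairs(x: np.ndarray) -> np.ndarray:
    """Stack single-ended rows with all pairwise differences ``row_i - row_j``.

    Pairs are ordered lexicographically with ``i < j``; for ``n`` input rows
    the output has ``n + n(n-1)/2`` rows.  Applied to the time-domain EMG
    before rectification.
    """
    x = np.atleast_2d(np.asarray(x))
    n = x.shape[0]
    if n < 1:
        raise ValueError("need at least one channel")
    if n == 1:
        return x.copy()
    i_idx, j_idx = np.triu_indices(n, k=1)
    return np.concatenate([x, x[i_idx] - x[j_idx]], axis=0)


def mav_features(
    emg: EmgRecording,
    window_ms: float = 300.0,
    frame_rate: float = 30.0,
    channel_labels: list[str] | None = None,
) -> FeatureMatrix:
    """Trailing-window mean absolute value at ``frame_rate`` Hz.

    Frame ``k`` (time ``k / frame_rate``) is the mean of ``|x|`` over the
    ``window_ms`` of samples ending at that time; frames whose window
    precedes the recording start use only the available samples.
    """
    if emg.n_samples == 0:
        raise ValueError("empty recording")
    w = int(round(window_ms / 1000.0 * emg.fs))
    if w < emg.fs / frame_rate:
        raise ValueError("MAV window must cover at least one frame period")
    n_frames = int(np.floor((emg.n_samples - 1) * frame_rate / emg.fs)) + 1
    sample_idx = np.floor(np.arange(n_frames) * emg.fs / frame_rate).astype(int)

    cs = np.concatenate(
        [np.zeros((emg.n_contacts, 1)), np.cumsum(np.abs(emg.data), axis=1)], axis=1
    )
    lo = np.maximum(sample_idx + 1 - w, 0)
    counts = sample_idx + 1 - lo
    values = (cs[:, sample_idx + 1] - cs[:, lo]) / counts
    return FeatureMatrix(values=values, frame_rate=frame_rate, channel_labels=channel_labels)


def extract_features(emg: EmgRecording, spec: FilterSpec | None = None) -> FeatureMatrix:
    """Full chain: filter, differential pairs, MAV. Convenience wrapper."""
    filtered = bandpass_notch(emg, spec)
    paired = differential_pairs(filtered.data)
    paired_rec = EmgRecording(data=paired, fs=emg.fs, contact_ids=pair_labels(filtered.contact_ids))
    return mav_features(paired_rec, channel_labels=paired_rec.contact_ids)


def align_lag(
    features: FeatureMatrix,
    kin: KinematicTrace,
    max_lag_s: float = 1.0,
) -> tuple[int, KinematicTrace]:
    """Estimate and remove the user's reaction lag.

    The lag (in frames, restricted to ``[0, max_lag_s]``) maximizes the
    normalized cross-correlation between the channel-mean of the
    mean-centered features and the DOF-mean of ``|kinematics|``.  The
    kinematics are then delayed by that lag — each target event is moved
    later to meet the EMG it evoked — with rest padding, so training pairs
    feature frame ``t`` with the target that produced it.
    """
    if features.n_frames != kin.n_frames:
        raise ValueError("features and kinematics must have equal frame counts")
    fr = features.frame_rate
    max_lag = int(round(max_lag_s * fr))
    f = features.values.mean(axis=0)
    f = f - f.mean()
    g = np.abs(kin.values).mean(axis=0)
    if np.allclose(g, 0.0):
        warnings.warn("all-zero kinematics: lag set to 0", stacklevel=2)
        return 0, KinematicTrace(values=kin.values.copy(), frame_rate=kin.frame_rate)
    g = g - g.mean()

    T = f.size
    best_lag, best_corr = 0, -np.inf
    for lag in range(min(max_lag, T - 2) + 1):
        a, b = f[lag:], g[: T - lag]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        corr = float(a @ b) / denom if denom > 0 else -np.inf
        if corr > best_corr:
            best_corr, best_lag = corr, lag
    shifted = np.zeros_like(kin.values)
    if best_lag == 0:
        shifted[:] = kin.values
    else:
        shifted[:, best_lag:] = kin.values[:, : T - best_lag]
    return best_lag, KinematicTrace(values=shifted, frame_rate=kin.frame_rate)


def shift_annotations(
    annotations: list[TrialAnnotation], lag_frames: int, n_frames: int
) -> list[TrialAnnotation]:
    """Trial spans after the kinematics were delayed by ``lag_frames``."""
    return [a.shifted(lag_frames, n_frames) for a in annotations]


def rest_frame_indices(
    annotations: list[TrialAnnotation],
    n_frames: int,
    guard_s: float = 0.7,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Frames outside every trial span (with a trailing guard band).

    The guard covers reaction lag plus the MAV window tail so that the
    "rest" frames carry no residual movement energy.
    """
    guard = int(round(guard_s * frame_rate))
    rest = np.ones(n_frames, dtype=bool)
    for a in annotations:
        rest[max(a.frame_start, 0) : min(a.frame_end + guard, n_frames)] = False
    return np.nonzero(rest)[0]


def baseline_subtract(features: FeatureMatrix, rest_frames: np.ndarray) -> FeatureMatrix:
    """Subtract each channel's mean over ``rest_frames`` (Kalman path).

    The result may be negative; that is expected for baseline-subtracted
    MAV and only the Kalman decoder consumes it.
    """
    rest_frames = np.asarray(rest_frames, dtype=int)
    if rest_frames.size == 0:
        raise ValueError("rest frame set is empty")
    baseline = features.values[:, rest_frames].mean(axis=1, keepdims=True)
    return FeatureMatrix(
        values=features.values - baseline,
        frame_rate=features.frame_rate,
        channel_labels=features.channel_labels,
    )


def rest_baseline_vector(features: FeatureMatrix, rest_frames: np.ndarray) -> np.ndarray:
    """Per-channel rest MAV (the vector subtracted by ``baseline_subtract``)."""
    rest_frames = np.asarray(rest_frames, dtype=int)
    if rest_frames.size == 0:
        raise ValueError("rest frame set is empty")
    return features.values[:, rest_frames].mean(axis=1)
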