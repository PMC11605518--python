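"""Modified Kalman filter (MKF) decoder.

A linear-Gaussian state-space decoder in the tradition of neural-decoding
Kalman filters: the state is the 12-DOF kinematic position, observations
are the selected baseline-subtracted MAV channels, and all four matrices
are estimated by least squares from training data.  The "modification" is
purely on the output: per-frame estimates inside a dead zone
``[-threshold, threshold]`` are zeroed (suppressing rest-state jitter) and
the result is clamped to the valid range ``[-1, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import N_DOF, DecodedTrace, KinematicTrace, clamp_unit
from .selection import SelectionResult


@dataclass
class KalmanModel:
    """Fitted MKF: state model (A, W), observation model (H, Q), output rules."""

    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    threshold: float = 0.2
    channel_indices: SelectionResult | None = None
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.W.shape != (n, n):
            raise ValueError("A and W must be square and equally sized")
        if self.H.shape[1] != n or self.Q.shape != (self.H.shape[0], self.H.shape[0]):
            raise ValueError("H/Q dimensions are inconsistent with the state size")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")

    @property
    def n_obs(self) -> int:
        return self.H.shape[0]


def threshold_modify(x: np.ndarray | float, threshold: float = 0.2) -> np.ndarray | float:
    """Dead-zone rule: zero while ``|x| <= threshold``, pass through beyond."""
    arr = np.asarray(x, dtype=float)
    out = np.where(np.abs(arr) <= threshold, 0.0, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def fit_kalman(
    features_selected: np.ndarray,
    kin: KinematicTrace,
    threshold: float = 0.2,
    channel_indices: SelectionResult | None = None,
    baseline: np.ndarray | None = None,
) -> KalmanModel:
    """Least-squares fit of the state-space decoder.

    ``A`` maps state t to t+1, ``H`` maps state to observation; ``W`` and
    ``Q`` are the corresponding residual covariances (the maximum-likelihood
    estimates for the linear-Gaussian model).  Features must already be
    lag-aligned, baseline-subtracted and channel-selected.
    """
    Z = np.atleast_2d(np.asarray(features_selected, dtype=float))
    X = kin.values
    T = X.shape[1]
    if Z.shape[1] != T:
        raise ValueError("features and kinematics must have equal frame counts")
    if T < N_DOF + Z.shape[0]:
        raise ValueError(f"too few frames ({T}) to fit the state-space model")

    X1, X2 = X[:, :-1], X[:, 1:]
    # A = argmin ||X2 - A X1||_F, via least squares (rank-safe).
    A = np.linalg.lstsq(X1.T, X2.T, rcond=None)[0].T
    W = (X2 - A @ X1) @ (X2 - A @ X1).T / max(T - 1, 1)

    H = np.linalg.lstsq(X.T, Z.T, rcond=None)[0].T
    R = Z - H @ X
    Q = R @ R.T / T
    # Guard against a singular observation covariance on degenerate data.
    Q += 1e-9 * np.eye(Q.shape[0])
    return KalmanModel(
        A=A, W=W, H=H, Q=Q, threshold=threshold, channel_indices=channel_indices, baseline=baseline
    )


def kalman_filter(
    A: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    Z: np.ndarray,
    initial_covariance: float = 10.0,
    gain_tol: float = 1e-9,
) -> np.ndarray:
    """Raw Kalman recursion: per-frame state estimates, no output shaping.

    Starts from the rest state (zeros) with covariance
    ``initial_covariance * I``.  For a time-invariant model the gain
    converges; once successive gains differ by less than ``gain_tol`` the
    steady-state gain is reused, which makes decoding O(frames) instead of
    O(frames x obs^3).  Set ``gain_tol=0`` to disable freezing.
    """
    n = A.shape[0]
    T = Z.shape[1]
    x = np.zeros(n)
    P = initial_covariance * np.eye(n)
    I = np.eye(n)
    out = np.empty((n, T))
    K_prev = None
    K = None
    frozen = False
    for t in range(T):
        x = A @ x
        if not frozen:
            P = A @ P @ A.T + W
            S = H @ P @ H.T + Q
            K = np.linalg.solve(S.T, (P @ H.T).T).T  # P H' S^-1
            if K_prev is not None and np.max(np.abs(K - K_prev)) < gain_tol:
                frozen = True
            K_prev = K
            P = (I - K @ H) @ P
        x = x + K @ (Z[:, t] - H @ x)
        out[:, t] = x
    return out


def predict_kalman(
    model: KalmanModel,
    features_selected: np.ndarray,
    initial_covariance: float = 10.0,
    gain_tol: float = 1e-9,
) -> DecodedTrace:
    """Run the Kalman recursion, then threshold and clamp the estimates."""
    Z = np.atleast_2d(np.asarray(features_selected, dtype=float))
    if Z.shape[0] != model.n_obs:
        raise ValueError(f"expected {model.n_obs} observation channels, got {Z.shape[0]}")
    out = kalman_filter(
        model.A, model.W, model.H, model.Q, Z,
        initial_covariance=initial_covariance, gain_tol=gain_tol,
    )
    modified = threshold_modify(out, model.threshold)
    return DecodedTrace(values=clamp_unit(modified))
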