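"""Convolutional regression network mapping EMG feature windows to kinematics.

The network consumes an ``N x 10`` image — all ``N`` MAV features at the
current frame and the nine preceding frames (30 Hz) — and regresses the 12
DOF positions.  Architecture: one convolutional layer with ten ``1 x 5``
kernels applied along time only (output feature map ``N x 6 x 10``), ReLU,
then two fully connected layers of ``2N`` units each with ReLU, and a
linear 12-unit regression output.  Training is stochastic gradient descent
with momentum at learning rate 1e-5, minimizing mean squared error, with
early stopping on a validation split drawn from 60/40 of the movement
trials.

Implemented directly on numpy (forward and backward passes are a few
matrix products), which keeps the dependency surface small and is fast
enough for the network's size on a CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .data import N_DOF, DecodedTrace, FeatureMatrix, TrainingSet, clamp_unit


@dataclass(frozen=True)
class CnnSpec:
    """Architecture hyperparameters; everything else follows from ``n_features``."""

    n_features: int
    window: int = 10
    conv_kernel: int = 5
    conv_filters: int = 10
    n_outputs: int = N_DOF

    def __post_init__(self) -> None:
        if self.window < self.conv_kernel:
            raise ValueError("window must be at least the convolution kernel length")
        if self.n_features < 1:
            raise ValueError("need at least one feature")

    @property
    def conv_out_len(self) -> int:
        """Temporal length of the conv feature map (valid convolution)."""
        return self.window - self.conv_kernel + 1

    @property
    def fc_width(self) -> int:
        """Width of both hidden fully connected layers: 2N."""
        return 2 * self.n_features

    @property
    def flat_size(self) -> int:
        return self.n_features * self.conv_out_len * self.conv_filters

    def parameter_count(self) -> int:
        n, w = self.n_features, self.fc_width
        conv = self.conv_filters * (self.conv_kernel + 1)
        fc1 = self.flat_size * w + w
        fc2 = w * w + w
        out = w * self.n_outputs + self.n_outputs
        return conv + fc1 + fc2 + out


@dataclass
class TrainConfig:
    """SGD-with-momentum training settings."""

    learning_rate: float = 1e-5
    momentum: float = 0.9
    batch_size: int = 32
    patience: int = 20
    train_frac: float = 0.6
    max_epochs: int = 100
    seed: int = 0
    standardize: bool = True
    window_stride: int = 1
    max_windows: int | None = None
    #: Optional cap on total window visits (epochs x training windows).
    #: Equalizes optimizer work across training-set sizes; early stopping
    #: still applies within the budget.
    visit_budget: int | None = None
    #: Optional cap on validation windows (uniform subsample).
    max_val_windows: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


class CnnModel:
    """Weights plus (optional) feature standardization statistics."""

    def __init__(self, spec: CnnSpec, params: dict[str, np.ndarray]):
        self.spec = spec
        self.params = params
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None
        self.history: dict = {}

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_cnn(spec: CnnSpec, seed: int = 0) -> CnnModel:
    """He-initialized network with the exact layer shapes of the spec."""
    rng = np.random.default_rng(seed)
    f, k = spec.conv_filters, spec.conv_kernel
    w, flat = spec.fc_width, spec.flat_size

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    params = {
        "Wc": he((f, k), k),
        "bc": np.zeros(f, dtype=np.float32),
        "W1": he((flat, w), flat),
        "b1": np.zeros(w, dtype=np.float32),
        "W2": he((w, w), w),
        "b2": np.zeros(w, dtype=np.float32),
        # Small output-layer init: predictions start near the rest posture
        # (the marginal mode of the targets) instead of random O(1) values.
        "W3": (rng.standard_normal((w, spec.n_outputs)) * 0.01).astype(np.float32),
        "b3": np.zeros(spec.n_outputs, dtype=np.float32),
    }
    return CnnModel(spec, params)


def _forward(params: dict, spec: CnnSpec, X: np.ndarray, cache: bool = False):
    """Forward pass on a batch of windows ``X`` shaped (B, N, window)."""
    B = X.shape[0]
    Xw = np.lib.stride_tricks.sliding_window_view(X, spec.conv_kernel, axis=2)
    Xwf = np.ascontiguousarray(Xw).reshape(-1, spec.conv_kernel)
    # (B*N*6, kernel) @ (kernel, filters) -> conv map (B, N, 6, filters)
    z0 = (Xwf @ params["Wc"].T).reshape(B, spec.n_features, spec.conv_out_len, spec.conv_filters)
    z0 += params["bc"]
    a0 = np.maximum(z0, 0.0)
    flat = a0.reshape(B, -1)
    h1 = np.maximum(flat @ params["W1"] + params["b1"], 0.0)
    h2 = np.maximum(h1 @ params["W2"] + params["b2"], 0.0)
    y = h2 @ params["W3"] + params["b3"]
    if cache:
        return y, (Xwf, a0, flat, h1, h2)
    return y


def _alloc_grads(params: dict) -> dict:
    return {k: np.empty_like(v) for k, v in params.items()}


def _flat_views(params: dict) -> tuple[np.ndarray, dict]:
    """Pack parameters into one flat float32 buffer; dict values are views.

    Lets the SGDM update run as a handful of whole-buffer in-place ops
    instead of per-parameter calls.
    """
    total = sum(v.size for v in params.values())
    flat = np.empty(total, dtype=np.float32)
    views = {}
    offset = 0
    for key, value in params.items():
        seg = flat[offset : offset + value.size]
        seg[:] = value.ravel()
        views[key] = seg.reshape(value.shape)
        offset += value.size
    return flat, views


def _backward(params: dict, spec: CnnSpec, caches, dY: np.ndarray, out: dict | None = None) -> dict:
    """Gradients of the half-SSE loss; writes into ``out`` buffers if given."""
    Xwf, a0, flat, h1, h2 = caches
    g = out if out is not None else _alloc_grads(params)
    np.matmul(h2.T, dY, out=g["W3"])
    np.sum(dY, axis=0, out=g["b3"])
    dh2 = dY @ params["W3"].T
    dh2 *= h2 > 0
    np.matmul(h1.T, dh2, out=g["W2"])
    np.sum(dh2, axis=0, out=g["b2"])
    dh1 = dh2 @ params["W2"].T
    dh1 *= h1 > 0
    np.matmul(flat.T, dh1, out=g["W1"])
    np.sum(dh1, axis=0, out=g["b1"])
    dflat = dh1 @ params["W1"].T
    dz0 = dflat.reshape(a0.shape)
    dz0 = dz0 * (a0 > 0)
    dz0f = dz0.reshape(-1, spec.conv_filters)
    np.matmul(dz0f.T, Xwf, out=g["Wc"])
    np.sum(dz0f, axis=0, out=g["bc"])
    return g


class EarlyStopper:
    """Stop when the validation loss has not decreased for ``patience`` checks."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0
        self.n_checks = 0

    def update(self, loss: float) -> bool:
        """Record one validation check; return True when training should stop."""
        self.n_checks += 1
        if loss < self.best:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def split_trials_by_movement(
    annotations, train_frac: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """60/40 split of trial indices, stratified by movement.

    Raises if any movement has a single trial (it could not appear in both
    partitions).
    """
    by_movement: dict = {}
    for idx, a in enumerate(annotations):
        by_movement.setdefault(a.movement_id, []).append(idx)
    train, val = [], []
    for movement_id in sorted(by_movement):
        trials = by_movement[movement_id]
        if len(trials) < 2:
            raise ValueError(
                f"movement {movement_id!r} has a single trial; cannot split train/validation"
            )
        order = rng.permutation(len(trials))
        n_train = max(1, min(len(trials) - 1, int(round(train_frac * len(trials)))))
        train.extend(trials[i] for i in order[:n_train])
        val.extend(trials[i] for i in order[n_train:])
    return sorted(train), sorted(val)


def _frame_owner(annotations, n_frames: int) -> np.ndarray:
    """Assign every frame to a trial (rest frames go with the preceding trial)."""
    owner = np.zeros(n_frames, dtype=int)
    starts = [a.frame_start for a in annotations]
    bounds = starts[1:] + [n_frames]
    for trial, (start, end) in enumerate(zip(starts, bounds)):
        owner[start:end] = trial
    # Lead-in rest belongs to the first trial.
    owner[: starts[0]] = 0
    return owner


def _window_tensor(padded: np.ndarray, frames: np.ndarray, window: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(padded, window, axis=1)
    return np.ascontiguousarray(view[:, frames].transpose(1, 0, 2), dtype=np.float32)


def _subsample(idx: np.ndarray, cap: int | None) -> np.ndarray:
    if cap is None or idx.size <= cap:
        return idx
    take = np.linspace(0, idx.size - 1, cap).round().astype(int)
    return idx[np.unique(take)]


def train_cnn(model: CnnModel, train_set: TrainingSet, config: TrainConfig) -> CnnModel:
    """Train with SGDM + early stopping; returns the best-validation model.

    The 60/40 split is over movement trials, not frames, so validation
    frames come from whole held-out trials.  Deterministic given
    ``config.seed``.
    """
    spec = model.spec
    feats = train_set.features
    if feats.n_features != spec.n_features:
        raise ValueError("feature count does not match the model spec")
    rng = np.random.default_rng(config.seed)
    train_trials, val_trials = split_trials_by_movement(
        train_set.annotations, config.train_frac, rng
    )
    owner = _frame_owner(train_set.annotations, feats.n_frames)
    in_train = np.isin(owner, train_trials)
    frames = np.arange(feats.n_frames)
    train_idx = _subsample(frames[in_train][:: config.window_stride], config.max_windows)
    val_cap = config.max_val_windows
    if val_cap is None and config.max_windows is not None:
        val_cap = max(1, config.max_windows // 2)
    val_idx = _subsample(frames[~in_train][:: config.window_stride], val_cap)

    values = feats.values
    if config.standardize:
        mean = values[:, train_idx].mean(axis=1, keepdims=True)
        std = values[:, train_idx].std(axis=1, keepdims=True)
        std = np.where(std > 1e-8, std, 1.0)
        values = (values - mean) / std
    padded = np.concatenate(
        [np.repeat(values[:, :1], spec.window - 1, axis=1), values], axis=1
    )
    Xtr = _window_tensor(padded, train_idx, spec.window)
    Xval = _window_tensor(padded, val_idx, spec.window)
    Ytr = train_set.kinematics.values[:, train_idx].T.astype(np.float32)
    Yval = train_set.kinematics.values[:, val_idx].T.astype(np.float32)

    pflat, params = _flat_views(model.params)
    vflat = np.zeros_like(pflat)
    gflat, grads = _flat_views(model.params)  # buffer reused; init values ignored
    stopper = EarlyStopper(config.patience)
    best_params = model.copy_params()
    history = {"train_loss": [], "val_loss": []}

    def loss_on(X, Y, batch=4096):
        total = 0.0
        for lo in range(0, X.shape[0], batch):
            pred = _forward(params, spec, X[lo : lo + batch])
            diff = pred - Y[lo : lo + batch]
            total += float(0.5 * np.einsum("ij,ij->", diff, diff))
        return total / max(X.shape[0], 1)

    n_train = Xtr.shape[0]
    n_epochs = config.max_epochs
    if config.visit_budget is not None:
        n_epochs = min(n_epochs, max(1, int(round(config.visit_budget / max(n_train, 1)))))
    lr, mom = config.learning_rate, config.momentum
    for _epoch in range(n_epochs):
        order = rng.permutation(n_train)
        Xp, Yp = Xtr[order], Ytr[order]  # contiguous batches below are views
        epoch_loss = 0.0
        for lo in range(0, n_train, config.batch_size):
            Xb = Xp[lo : lo + config.batch_size]
            Yb = Yp[lo : lo + config.batch_size]
            pred, caches = _forward(params, spec, Xb, cache=True)
            diff = pred - Yb
            d = diff.ravel()
            epoch_loss += 0.5 * float(d @ d)
            _backward(params, spec, caches, diff / Xb.shape[0], out=grads)
            vflat *= mom
            gflat *= lr
            vflat -= gflat
            pflat += vflat
        history["train_loss"].append(epoch_loss / n_train)
        val_loss = loss_on(Xval, Yval)
        history["val_loss"].append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_params = {k: v.copy() for k, v in params.items()}
        if stop:
            break

    out = CnnModel(spec, best_params)
    if config.standardize:
        out.feature_mean = mean
        out.feature_std = std
    out.history = {**history, "n_checks": stopper.n_checks}
    return out


def predict_cnn(model: CnnModel, features: FeatureMatrix, batch: int = 2048) -> DecodedTrace:
    """Per-frame decoding; the first 9 frames use edge-replicated history.

    Outputs are clamped to [-1, 1].
    """
    spec = model.spec
    if features.n_features != spec.n_features:
        raise ValueError("feature count does not match the model spec")
    values = features.values
    if model.feature_mean is not None:
        values = (values - model.feature_mean) / model.feature_std
    padded = np.concatenate(
        [np.repeat(values[:, :1], spec.window - 1, axis=1), values], axis=1
    )
    frames = np.arange(features.n_frames)
    out = np.empty((spec.n_outputs, features.n_frames))
    for lo in range(0, frames.size, batch):
        X = _window_tensor(padded, frames[lo : lo + batch], spec.window)
        out[:, lo : lo + batch] = _forward(model.params, spec, X).T
    return DecodedTrace(values=clamp_unit(out), frame_rate=features.frame_rate)
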