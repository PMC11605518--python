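"""Stepwise Gram-Schmidt forward channel selection.

Reduces the full MAV feature set (hundreds of single-ended + differential
channels) to a small subset for the Kalman decoder.  At each step every
remaining channel is residualized against the span of the already-selected
channels, and the channel whose residual carries the most kinematic
information — the sum over DOFs of the squared correlation between the
residual and each kinematic trace — is selected.  This is the standard
forward orthogonal-least-squares criterion generalized to 12 targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, KinematicTrace


@dataclass
class SelectionResult:
    """Ordered selected feature indices and their per-step scores."""

    selected_indices: list[int]
    scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected_indices)

    def __iter__(self):
        return iter(self.selected_indices)


def gram_schmidt_select(
    features: FeatureMatrix,
    kin: KinematicTrace,
    k: int = 48,
    tol: float = 1e-10,
) -> SelectionResult:
    """Forward-select ``k`` channels by orthogonalized correlation score.

    Channels are mean-centered before selection; ties are broken by the
    lowest channel index; channels whose residual norm falls below
    ``tol`` times their original norm are treated as linearly dependent
    and excluded.  Returns fewer than ``k`` indices (with a warning) if
    the feature matrix runs out of rank first.
    """
    if features.n_frames != kin.n_frames:
        raise ValueError("features and kinematics must be frame-aligned")
    if k > features.n_features:
        raise ValueError("cannot select more channels than exist")

    X = features.values - features.values.mean(axis=1, keepdims=True)
    X = np.array(X, dtype=float)
    Y = kin.values - kin.values.mean(axis=1, keepdims=True)
    y_norm = np.linalg.norm(Y, axis=1)
    valid_dof = y_norm > 0
    Yn = np.zeros_like(Y)
    Yn[valid_dof] = Y[valid_dof] / y_norm[valid_dof, None]

    orig_norm = np.linalg.norm(X, axis=1)
    active = orig_norm > 0
    selected: list[int] = []
    scores: list[float] = []
    for _ in range(k):
        norms = np.linalg.norm(X, axis=1)
        usable = active & (norms > tol * np.maximum(orig_norm, 1e-300))
        if not np.any(usable):
            warnings.warn(
                f"rank exhausted after {len(selected)} channels (requested {k})",
                stacklevel=2,
            )
            break
        corr = (X @ Yn.T) / np.where(norms > 0, norms, 1.0)[:, None]
        score = np.einsum("ij,ij->i", corr, corr)
        score[~usable] = -np.inf
        best = int(np.argmax(score))  # argmax takes the lowest index on ties
        selected.append(best)
        scores.append(float(score[best]))
        u = X[best] / norms[best]
        X -= np.outer(X @ u, u)
        X[best] = 0.0
        active[best] = False
    return SelectionResult(selected_indices=selected, scores=scores)
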