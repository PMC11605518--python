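"""Optional figures for the aggregation study (requires matplotlib).

Violin plots of per-trial intended/unintended RMSE by decoder and
aggregation size, and a scatter of per-DOF robustness slopes — the
simulation-study analogues of the standard accuracy/robustness panels.
Install with the ``plots`` extra: ``pip install emgagg[plots]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("plotting requires matplotlib (install the 'plots' extra)") from err
    return plt


def plot_rmse_violins(metrics: pd.DataFrame, out_path: str | Path) -> Path:
    """Per-trial RMSE distributions for every decoder x aggregation size."""
    plt = _require_matplotlib()
    decoders = sorted(metrics["decoder"].unique())
    sizes = sorted(metrics["n_aggregated"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, column, title in zip(
        axes, ("intended_rmse", "unintended_rmse"), ("Intended RMSE", "Unintended RMSE")
    ):
        groups, labels = [], []
        for dec in decoders:
            for K in sizes:
                sel = metrics[(metrics["decoder"] == dec) & (metrics["n_aggregated"] == K)]
                groups.append(sel[column].to_numpy())
                labels.append(f"{dec}\nK={K}")
        parts = ax.violinplot(groups, showmedians=True, showextrema=False)
        for body in parts["bodies"]:
            body.set_alpha(0.6)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
        ax.set_title(title)
        ax.set_ylabel("RMSE (normalized position)")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_robustness_slopes(slopes: pd.DataFrame, out_path: str | Path, decoder: str = "cnn") -> Path:
    """Per-DOF RMSE-per-day slopes versus aggregation size (one point per
    subject x DOF, horizontal bar at the median)."""
    plt = _require_matplotlib()
    sel = slopes[slopes["decoder"] == decoder]
    sizes = sorted(sel["n_aggregated"].unique())
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, K in enumerate(sizes):
        vals = sel[sel["n_aggregated"] == K]["slope"].to_numpy()
        x = i + 1 + rng.uniform(-0.12, 0.12, size=vals.size)
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
        ax.hlines(np.median(vals), i + 0.75, i + 1.25, color="k", lw=2)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(range(1, len(sizes) + 1), [f"K={K}" for K in sizes])
    ax.set_ylabel("RMSE per day")
    ax.set_title(f"{decoder.upper()} robustness slopes")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
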