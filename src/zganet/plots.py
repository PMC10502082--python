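"""Minimal diagnostic plots: optimization waterfall and residual heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_waterfall", "plot_residual_heatmap"]


def plot_waterfall(fit_collection, path, n_best: int = 100):
    """Sorted objectives of the converged optimization runs."""
    w = fit_collection.waterfall[:n_best]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(np.arange(1, w.size + 1), w, "o-", ms=3)
    ax.set_xlabel("sorted optimization run")
    ax.set_ylabel("objective (-2 log L + prior)")
    ax.set_title(f"waterfall ({w.size} runs, cluster {fit_collection.cluster_size})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_residual_heatmap(contingency, path, threshold: float = 4.0):
    """Pearson residuals of a contingency result; strong positives outlined."""
    R = contingency.residuals
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * R.shape[1], 1.2 + 0.6 * R.shape[0]))
    vmax = max(abs(R.to_numpy()).max(), threshold)
    im = ax.imshow(R.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(R.shape[1]), R.columns, rotation=45, ha="right")
    ax.set_yticks(range(R.shape[0]), R.index)
    for i, r in enumerate(R.index):
        for j, c in enumerate(R.columns):
            if (str(r), str(c)) in [tuple(map(str, cell)) for cell in contingency.strong_positive]:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, lw=2, ec="k"))
    fig.colorbar(im, ax=ax, label="Pearson residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
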