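"""Figure helpers: sorted response heatmaps and information curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import ResponseMap, sort_by_peak

__all__ = ["plot_response_map", "plot_ranked_info", "plot_per_stimulus_info"]


def plot_response_map(
    resp: ResponseMap, path: str | Path | None = None, *, sort: bool = True, title: str = ""
):
    """Heatmap of output rates, cells sorted by the location of their peak."""
    order = sort_by_peak(resp) if sort else np.arange(resp.n_cells)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        resp.rates[:, order].T,
        aspect="auto",
        origin="lower",
        cmap="viridis",
        extent=(resp.f0_labels[0], resp.f0_labels[-1], 0, resp.n_cells),
        vmin=0.0,
        vmax=1.0,
    )
    ax.set_xlabel("stimulus F0 (Hz)")
    ax.set_ylabel("output cell (peak-sorted)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="firing rate")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ranked_info(curves: dict[str, np.ndarray], path: str | Path | None = None):
    """Ranked single-cell information curves (one line per condition)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(np.arange(1, curve.size + 1), curve, label=label)
    ax.set_xlabel("cell rank")
    ax.set_ylabel("single-cell information (bits)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_per_stimulus_info(
    f0s: np.ndarray, profiles: dict[str, np.ndarray], path: str | Path | None = None
):
    """Best-cell information per stimulus across the F0 range."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(f0s, prof, marker="o", ms=3, label=label)
    ax.set_xlabel("stimulus F0 (Hz)")
    ax.set_ylabel("max single-cell information (bits)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
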