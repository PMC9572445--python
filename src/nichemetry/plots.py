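"""Figure helpers for the analysis drivers (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .geometry import LabelMask, isotropic_niche_ratio
from .tracking import GradientMap, Track

__all__ = [
    "plot_packing_density",
    "plot_niche_ratio",
    "plot_gradient_map",
    "plot_quench",
]


def plot_packing_density(summary: pd.DataFrame, path: str | Path) -> None:
    """Density per unit area vs wall separation, one curve per niche size."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    for ax, em in zip(axes, ("nuclei", "cytoplasm")):
        sub = summary[summary["endmember"] == em]
        for niche, g in sub.groupby("niche_size"):
            g = g.sort_values("wall_separation")
            ax.plot(g["wall_separation"], g["mean_density"], "o-", label=f"{niche:g} µm")
        ax.set_xlabel("wall separation (µm)")
        ax.set_title(em)
    axes[0].set_ylabel("abundance per 200 µm²")
    axes[0].legend(title="niche size", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_niche_ratio(summary: pd.DataFrame, path: str | Path,
                     niche_depth: float = 7.5) -> None:
    """Measured niche-contact ratio vs separation with the isotropic curve."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    seps = np.linspace(16, 60, 100)
    iso = [isotropic_niche_ratio(s, niche_depth) for s in seps]
    for ax, em in zip(axes, ("nuclei", "cytoplasm")):
        sub = summary[summary["endmember"] == em]
        key = "niche_size" if "niche_size" in sub.columns else None
        if key:
            for niche, g in sub.groupby(key):
                g = g.sort_values("wall_separation")
                ax.plot(g["wall_separation"], g["niche_ratio"], "o-", label=f"{niche:g} µm")
        else:
            g = sub.sort_values("wall_separation")
            ax.plot(g["wall_separation"], g["niche_ratio"], "o-", label="measured")
        ax.plot(seps, iso, "k--", lw=1, label="isotropic")
        ax.set_xlabel("wall separation (µm)")
        ax.set_ylim(0, 1.05)
        ax.set_title(em)
    axes[0].set_ylabel("niche-contact ratio")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gradient_map(
    gm: GradientMap,
    path: str | Path,
    mask: LabelMask | None = None,
    tracks: list[Track] | None = None,
    title: str = "",
) -> None:
    """Motility field, blue (stationary) to red, with scaffold outline overlay."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(gm.field, cmap="jet", vmin=0, vmax=gm.display_max,
                   interpolation="nearest")
    if mask is not None:
        wall = (mask.grid == 1).astype(float)
        ax.contour(wall, levels=[0.5], colors="white", linewidths=0.4)
    if tracks:
        n_t = max(t for tr in tracks for t, _, _ in tr.positions) + 1
        cmap = plt.cm.plasma(np.linspace(0, 1, n_t))
        for tr in tracks:
            for t, x, y in tr.positions:
                ax.plot(x, y, "o", ms=3, mfc="none", mec=cmap[t], mew=0.8)
    fig.colorbar(im, ax=ax, label="total movement (µm)")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_quench(t: np.ndarray, intensity: np.ndarray, fitted: np.ndarray,
                path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.6))
    ax.semilogy(t, intensity, "o", label="integrated intensity")
    ax.semilogy(t, fitted, "-", label="exponential fit")
    ax.set_xlabel("UV treatment time (min)")
    ax.set_ylabel("scaffold autofluorescence (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
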