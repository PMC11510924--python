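"""Figure helpers: phantom permittivity raster and PCA scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import pca_project
from .phantom import Phantom, rasterize
from .scenarios import Dataset

__all__ = ["plot_phantom", "plot_pca"]


def plot_phantom(phantom: Phantom, path, n: int = 256) -> Path:
    """Save a two-panel (real part / loss part) permittivity map as PNG."""
    x, z, eps = rasterize(phantom, n)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), constrained_layout=True)
    for ax, data, title in (
        (axes[0], eps.real, "relative permittivity"),
        (axes[1], -eps.imag, "loss term"),
    ):
        im = ax.pcolormesh(x, z, data, shading="auto")
        ax.set_aspect("equal")
        ax.set_title(title)
        ax.set_xlabel("x (cm)")
        ax.set_ylabel("z (cm)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path).with_suffix(".png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_pca(dataset: Dataset, path, split: str = "train") -> Path:
    """Scatter the first two principal axes of one split, colored by class.

    Train and test are projected separately, matching how the published
    figures are produced.
    """
    sub = dataset.part(split) if split else dataset
    coords, evr = pca_project(sub.features, n_components=2)
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    for label, name, marker in ((1, "healthy", "o"), (-1, "injured", "x")):
        m = sub.labels == label
        ax.scatter(coords[m, 0], coords[m, 1], s=8, marker=marker, label=name)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.set_title(f"{split or 'all'} split")
    ax.legend()
    path = Path(path).with_suffix(".png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
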