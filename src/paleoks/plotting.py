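"""Optional figures: Ks histogram with mixture overlay, SiZer raster."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap
from scipy.stats import norm

from .mixture_peaks import MixtureModel
from .sizer import DECREASE, FLAT, INCREASE, SPARSE, SizerMap

__all__ = ["plot_ks_histogram", "plot_sizer_map"]


def plot_ks_histogram(
    values: Sequence[float], model: Optional[MixtureModel], path
) -> None:
    x = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(x, bins=60, density=True, color="lightgray", edgecolor="gray")
    if model is not None:
        grid = np.linspace(0, x.max(), 400)
        dens = np.zeros_like(grid)
        for w, mu, sd in zip(model.weights, model.means, model.sds):
            dens += w * norm.pdf(grid, mu, sd)
        ax.plot(grid, dens, color="black", lw=1.5, label=f"mixture (k={model.k})")
        for mu in model.means:
            ax.axvline(mu, color="steelblue", ls="--", lw=0.8)
        ax.legend()
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sizer_map(smap: SizerMap, path) -> None:
    # conventional SiZer colors: blue increase, red decrease, pink flat,
    # gray where data are too sparse
    code_to_idx = {DECREASE: 0, FLAT: 1, INCREASE: 2, SPARSE: 3}
    img = np.vectorize(code_to_idx.get)(smap.cells)
    cmap = ListedColormap(["red", "pink", "blue", "lightgray"])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.pcolormesh(
        smap.x_grid, np.log10(smap.bandwidths), img, cmap=cmap, vmin=0, vmax=3
    )
    ax.set_xlabel("Ks")
    ax.set_ylabel("log10 bandwidth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
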