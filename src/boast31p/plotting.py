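"""Minimal rendering helpers (heatmaps and profiles to image files)."""

from __future__ import annotations

import numpy as np

__all__ = ["save_heatmap", "save_profile"]


def save_heatmap(df, value: str, x: str, y: str, path, title: str = "") -> None:
    """Pivot a long-format sweep DataFrame and render ``value`` over (x, y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot_table(index=y, columns=x, values=value)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, np.log10(np.abs(pivot.to_numpy()) + 1e-12))
    fig.colorbar(im, ax=ax, label=f"log10 |{value}|")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_profile(x, y, path, xlabel: str = "", ylabel: str = "", title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(x, y)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
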