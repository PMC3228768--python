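"""Simple map/curve rendering for experiment outputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def render_entropy_maps(map_table: pd.DataFrame, path: str | Path) -> None:
    """Render Lambert-projected entropy maps, one panel per (flutter, sigma, strength)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = ["flutter_hz", "sigma_db", "echo_strength_db"]
    groups = list(map_table.groupby(keys, sort=True))
    n = len(groups)
    ncols = min(n, 4)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.2 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, ((f, s, a), g) in zip(axes.ravel(), groups):
        ax.set_axis_on()
        sc = ax.scatter(
            g["lambert_x"], g["lambert_y"], c=g["mean_entropy_bits"], s=8, cmap="viridis"
        )
        ax.set_title(f"{f:g} Hz, sigma {s:g} dB, A {a:g} dB", fontsize=8)
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(sc, ax=ax, shrink=0.8, label="bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_performance_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Render performance (%) versus flutter rate, one line per noise level/mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (sigma, mode), g in curves.groupby(["sigma_db", "mode"]):
        g = g.sort_values("flutter_hz")
        ax.plot(g["flutter_hz"], g["performance_pct"], marker="o", label=f"sigma {sigma:g} dB ({mode})")
    ax.axhline(90.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("flutter rate (Hz)")
    ax.set_ylabel("performance (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
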