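"""Basic report figures: percent-of-guidelines dot plots.

Rendering is optional — data outputs never depend on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["dot_plot", "scope_plot"]


def _base(df: pd.DataFrame, color, ax):
    order = df.sort_values("percent_met").reset_index(drop=True)
    ax.scatter(range(len(order)), order["percent_met"], s=14, c=color, zorder=3)
    ax.axhline(100.0, color="green", lw=1.2, label="100% of guideline amount")
    ax.set_xlabel("countries (ranked)")
    ax.set_ylabel("% of guideline amount in standard")
    return order


def dot_plot(scores: pd.DataFrame, path: str | Path) -> Path:
    """One dot per country, ranked by percent of guidelines met."""
    fig, ax = plt.subplots(figsize=(7, 4))
    _base(scores, "darkorange", ax)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scope_plot(scores: pd.DataFrame, path: str | Path) -> Path:
    """Dot plot coloured by legislation scope (both streams vs one)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    order = scores.sort_values("percent_met").reset_index(drop=True)
    both = order["scope"] == "both"
    ax.scatter(order.index[both], order.loc[both, "percent_met"], s=14,
               c="steelblue", label="household + processed food salt", zorder=3)
    ax.scatter(order.index[~both], order.loc[~both, "percent_met"], s=18,
               c="crimson", label="single salt stream", zorder=4)
    ax.axhline(100.0, color="green", lw=1.2)
    ax.set_xlabel("countries (ranked)")
    ax.set_ylabel("% of guideline amount in standard")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
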