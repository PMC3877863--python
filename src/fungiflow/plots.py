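"""Headless-safe report figures: density overlays and rank plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fungiflow.mixture import MixtureModel, mixture_density
from fungiflow.quantify import ExpressionVector
from fungiflow.zipf import ZipfFit

DEFAULT_BIN_WIDTH = 0.25  # log2 units


def plot_density_overlay(
    vector: ExpressionVector,
    model: MixtureModel,
    path: str | Path,
    bin_width: float = DEFAULT_BIN_WIDTH,
    title: str = "",
) -> None:
    """Histogram of log2 expression with the fitted mixture overlaid.

    The total density is drawn in red over grey histogram bars; each
    component curve (weighted by its mixing proportion) is drawn beneath it.
    """
    x = vector.to_numpy()
    lo, hi = x.min(), x.max()
    bins = np.arange(np.floor(lo), np.ceil(hi) + bin_width, bin_width)
    grid = np.linspace(lo - 1, hi + 1, 800)
    total, components = mixture_density(model, grid)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=bins, density=True, color="0.75", edgecolor="0.6")
    for comp in components:
        ax.plot(grid, comp, lw=1.2)
    ax.plot(grid, total, color="red", lw=2)
    ax.set_xlabel("normalized log2 expression")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rank_expression(
    series: pd.DataFrame,
    fit: ZipfFit,
    path: str | Path,
    title: str = "",
) -> None:
    """Log2 expression vs log2 rank with the regression line and gradient label."""
    x = series["log2_rank"].to_numpy()
    y = series["log2_value"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, y, ".", ms=2, color="0.4")
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, fit.intercept + fit.gradient * xs, color="red", lw=1.5)
    ax.text(
        0.97,
        0.95,
        f"gradient = {fit.gradient:.3f}",
        transform=ax.transAxes,
        ha="right",
        va="top",
    )
    ax.set_xlabel("log2 expression rank")
    ax.set_ylabel("normalized log2 expression")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
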