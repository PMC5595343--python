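"""Diagnostic figures: feeding-strategy diagram, mixing polygon, posteriors."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dietmix.mixing_model import MixingPosterior, summarize_posterior
from dietmix.mixing_polygon import PolygonResult


def amundsen_plot(points: pd.DataFrame, ax=None):
    """Costello-Amundsen diagram: prey-specific abundance vs occurrence.

    Upper-left = specialisation on rare prey, upper-right = dominant
    prey, lower-right = generalist feeding.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(points["pctO"], points["pctP"], s=25, color="k", zorder=3)
    for row in points.itertuples(index=False):
        ax.annotate(row.taxon, (row.pctO, row.pctP), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Frequency of occurrence %O")
    ax.set_ylabel("Prey-specific abundance %P")
    ax.text(2, 97, "specialist", fontsize=8, va="top")
    ax.text(98, 3, "generalist", fontsize=8, ha="right")
    return ax


def polygon_plot(result: PolygonResult, consumers: np.ndarray, ax=None):
    """Mixing-region probability contours (10% steps), consumers, sources."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if result.surface is not None:
        cs = ax.contour(
            result.grid_x, result.grid_y, result.surface,
            levels=np.arange(0.1, 1.0, 0.1), colors="grey", linewidths=0.7,
        )
        ax.clabel(cs, fontsize=6, fmt="%.1f")
    xy = np.atleast_2d(np.asarray(consumers, dtype=float))
    ax.scatter(xy[:, 0], xy[:, 1], s=12, color="k", label="consumers")
    if result.mean_vertices is not None:
        ax.scatter(result.mean_vertices[:, 0], result.mean_vertices[:, 1],
                   marker="x", s=60, color="tab:red", label="sources (TDF-corrected)")
    ax.set_xlabel("$\\delta^{13}$C (‰)")
    ax.set_ylabel("$\\delta^{15}$N (‰)")
    ax.legend(fontsize=8)
    return ax


def posterior_interval_plot(posterior: MixingPosterior, ax=None):
    """Per-source medians with nested 50/75/95% credible intervals."""
    summary = summarize_posterior(posterior)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    y = np.arange(len(summary))[::-1]
    for width, (lo, hi) in zip((2.0, 4.5, 8.0), (("lo95", "hi95"), ("lo75", "hi75"), ("lo50", "hi50"))):
        ax.hlines(y, summary[lo], summary[hi], lw=width, color="tab:blue", alpha=0.6)
    ax.plot(summary["median"], y, "o", color="k", ms=4)
    ax.set_yticks(y)
    ax.set_yticklabels(summary["source"])
    ax.set_xlim(0, 1)
    ax.set_xlabel("Diet proportion")
    return ax
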