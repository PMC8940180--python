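"""Figures: chronospace ordinations, node-age ranges, LTT and delta trends.

All functions return a matplotlib Figure; callers decide the backend and
file format (the CLI writes SVG).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bgpca import BgPCAResult

__all__ = [
    "plot_chronospace",
    "plot_node_ranges",
    "plot_ltt",
    "plot_delta_trend",
]


def plot_chronospace(result: BgPCAResult, metadata: pd.DataFrame, ax=None):
    """Scatter of the first two bgPC axes, colored by factor level, with
    level centroids joined by lines whose width scales with the inverse
    of the centroid distance (thicker = more similar)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    labels = metadata[result.factor].astype(str).to_numpy()
    two_d = result.n_axes >= 2
    for lv in result.levels:
        mask = labels == lv
        x = result.scores[mask, 0]
        y = result.scores[mask, 1] if two_d else np.zeros(mask.sum())
        ax.scatter(x, y, s=4, alpha=0.4, label=lv)
    C = result.group_centroids.to_numpy()
    cx = C[:, 0]
    cy = C[:, 1] if two_d else np.zeros(len(C))
    dmat = result.centroid_distances.to_numpy()
    finite = dmat[dmat > 0]
    for i in range(len(C)):
        for j in range(i + 1, len(C)):
            if dmat[i, j] > 0 and finite.size:
                w = 3.0 * finite.min() / dmat[i, j]
                ax.plot([cx[i], cx[j]], [cy[i], cy[j]], "k-", lw=w, alpha=0.5)
    ax.scatter(cx, cy, marker="D", c="black", s=40, zorder=3)
    ve = result.variance_explained
    ax.set_xlabel(f"bgPC1 ({100 * ve[0]:.1f}% of total variance)" if len(ve) else "bgPC1")
    if two_d:
        ax.set_ylabel(f"bgPC2 ({100 * ve[1]:.1f}%)")
    ax.legend(title=result.factor, fontsize=8)
    ax.set_title(f"Chronospace: {result.factor}")
    fig.tight_layout()
    return fig


def plot_node_ranges(ranges: pd.DataFrame, top: int = 20, ax=None):
    """Dot-and-bar plot of the widest consensus age ranges across runs."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 0.3 * min(top, len(ranges)) + 1.5))
    else:
        fig = ax.figure
    sub = ranges.head(top)[::-1]
    y = np.arange(len(sub))
    ax.hlines(y, sub["min_age"], sub["max_age"], color="steelblue", lw=3)
    ax.plot(sub["min_age"], y, "|", color="navy")
    ax.plot(sub["max_age"], y, "|", color="navy")
    ax.set_yticks(y, [n[:40] for n in sub["node"]], fontsize=6)
    ax.set_xlabel("age (Myr)")
    ax.invert_xaxis()
    ax.set_title("Range of consensus node ages across runs")
    fig.tight_layout()
    return fig


def plot_ltt(curve: pd.DataFrame, events: dict[str, float] | None = None, ax=None):
    """Lineage-through-time step plot (log lineage count vs age), with
    optional vertical event lines such as mass-extinction boundaries."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.step(curve["age"], curve["lineages"], where="post", color="darkred")
    ax.set_yscale("log")
    ax.invert_xaxis()
    for name, age in (events or {}).items():
        ax.axvline(age, ls="--", color="grey", lw=1)
        ax.text(age, ax.get_ylim()[1], name, fontsize=7, ha="center", va="bottom")
    ax.set_xlabel("age (Myr)")
    ax.set_ylabel("lineages")
    fig.tight_layout()
    return fig


def plot_delta_trend(table: pd.DataFrame, coeffs, ax=None):
    """Mean gene-wise delta against dataset size with the fitted
    second-degree polynomial; positive deltas support topology T1."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.axhline(0.0, color="grey", lw=1)
    ax.scatter(table["k"], table["mean_delta"], color="black", s=18)
    ks = np.linspace(table["k"].min(), table["k"].max(), 200)
    ax.plot(ks, np.polyval(coeffs, ks), color="firebrick")
    ax.set_xlabel("dataset size (loci, by decreasing usefulness)")
    ax.set_ylabel("mean per-locus delta lnL")
    fig.tight_layout()
    return fig
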