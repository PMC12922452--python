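"""Publication-format figures: trait plots, ordination scatters, LD1 density.

All figures are single-page vector PDFs at 7.5 x 6 in.  Mensural traits
get violin plots with embedded boxplots (white dot = mean, bar = median,
whiskers at 1.5 x IQR); meristic traits get boxplots only.  Ordination
scatters can carry convex hulls for user-declared taxa, and two-group
DAPC (a single discriminant axis) falls back to per-group kernel density
curves over LD1.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import gaussian_kde

from .core_data import MENSURAL, PhenotypeError
from .multivariate import OrdinationResult

__all__ = ["FIGSIZE", "build_trait_figure", "trait_plot", "ordination_plot",
           "ld1_density_plot"]

FIGSIZE = (7.5, 6.0)  # inches


def _grouped(values, groups):
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups).astype(str)
    out = {}
    for label in sorted(set(g)):
        x = v[g == label]
        x = x[np.isfinite(x)]
        if x.size == 0:
            warnings.warn(f"group {label!r} has no data; omitted from plot")
            continue
        out[label] = x
    return out


def build_trait_figure(values, groups, kind: str,
                       letters: dict[str, str] | None = None,
                       colors: dict[str, str] | None = None,
                       title: str = ""):
    """Assemble the trait figure without saving (violin layer iff mensural)."""
    by = _grouped(values, groups)
    if not by:
        raise PhenotypeError("no group has data to plot")
    labels = list(by.keys())
    data = [by[k] for k in labels]
    fig, ax = plt.subplots(figsize=FIGSIZE)
    positions = np.arange(1, len(labels) + 1)
    if kind == MENSURAL:
        parts = ax.violinplot(data, positions=positions, showextrema=False)
        for body, label in zip(parts["bodies"], labels):
            if colors:
                body.set_facecolor(colors.get(label, "0.6"))
            body.set_alpha(0.6)
    bp = ax.boxplot(data, positions=positions, widths=0.18, whis=1.5,
                    patch_artist=True, showfliers=True)
    for patch, label in zip(bp["boxes"], labels):
        patch.set_facecolor(colors.get(label, "white") if colors else "white")
    for pos, x in zip(positions, data):
        ax.plot(pos, np.mean(x), "o", color="white", mec="black", zorder=5)
    if letters:
        lo, hi = ax.get_ylim()
        pad = 0.05 * (hi - lo)
        for pos, label, x in zip(positions, labels, data):
            if label in letters:
                ax.text(pos, x.max() + pad, letters[label],
                        ha="center", va="bottom", fontweight="bold")
        ax.set_ylim(lo, hi + 2 * pad)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_title(title)
    return fig


def trait_plot(values, groups, kind: str, path: str | Path,
               letters: dict[str, str] | None = None,
               colors: dict[str, str] | None = None,
               title: str = "") -> Path:
    """Violin+box (mensural) or box-only (meristic) per-group trait plot."""
    fig = build_trait_figure(values, groups, kind, letters, colors, title)
    fig.savefig(path, format="pdf", bbox_inches=None)
    plt.close(fig)
    return Path(path)


def _axis_label(kind: str, i: int, explained: np.ndarray) -> str:
    return f"{kind}{i+1} ({100*explained[i]:.1f}%)"


def ordination_plot(ord_res: OrdinationResult, path: str | Path,
                    hull_taxa=(), colors: dict[str, str] | None = None,
                    title: str = "") -> Path:
    """Axis-1 vs axis-2 score scatter with optional per-taxon convex hulls."""
    if ord_res.scores.shape[1] < 2:
        raise PhenotypeError("ordination plot needs at least 2 axes")
    g = ord_res.groups.astype(str)
    xy = ord_res.scores.iloc[:, :2].to_numpy()
    fig, ax = plt.subplots(figsize=FIGSIZE)
    for label in sorted(g.unique()):
        pts = xy[(g == label).to_numpy()]
        color = colors.get(label) if colors else None
        ax.scatter(pts[:, 0], pts[:, 1], label=label, color=color,
                   edgecolor="black", linewidth=0.3, s=35)
        if label in set(hull_taxa):
            if pts.shape[0] < 3:
                warnings.warn(f"hull for {label!r}: <3 points, drawing degenerate hull")
                ax.plot(pts[:, 0], pts[:, 1], "-", color=color, lw=1)
                continue
            try:
                hull = ConvexHull(pts)
                verts = np.append(hull.vertices, hull.vertices[0])
                ax.plot(pts[verts, 0], pts[verts, 1], "-", color=color, lw=1.2)
                ax.fill(pts[hull.vertices, 0], pts[hull.vertices, 1],
                        color=color, alpha=0.15)
            except QhullError:
                warnings.warn(f"hull for {label!r}: collinear points, drawing segment")
                ax.plot(pts[:, 0], pts[:, 1], "-", color=color, lw=1)
    ax.set_xlabel(_axis_label(ord_res.axis_kind, 0, ord_res.explained))
    ax.set_ylabel(_axis_label(ord_res.axis_kind, 1, ord_res.explained))
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title)
    fig.savefig(path, format="pdf")
    plt.close(fig)
    return Path(path)


def ld1_density_plot(scores, groups, path: str | Path,
                     colors: dict[str, str] | None = None,
                     title: str = "") -> Path:
    """Per-group kernel densities over the single discriminant axis (K = 2)."""
    by = _grouped(scores, groups)
    fig, ax = plt.subplots(figsize=FIGSIZE)
    for label, x in by.items():
        color = colors.get(label) if colors else None
        if x.size < 2 or np.ptp(x) == 0:
            warnings.warn(f"group {label!r}: density undefined, drawing rug marks")
            ax.plot(x, np.zeros_like(x), "|", ms=20, color=color, label=label)
            continue
        kde = gaussian_kde(x)  # Scott's rule bandwidth
        grid = np.linspace(x.min() - np.ptp(x) * 0.3, x.max() + np.ptp(x) * 0.3, 256)
        ax.fill_between(grid, kde(grid), alpha=0.4, color=color, label=label)
    ax.set_xlabel("LD1")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title)
    fig.savefig(path, format="pdf")
    plt.close(fig)
    return Path(path)
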