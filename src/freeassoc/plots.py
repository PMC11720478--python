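"""Visual outputs: the two-dimensional semantic map and faceted word clouds.

Both plots are frequency-aware: point, label and font sizes grow
monotonically with a target's response frequency, so the visual weight of
a word reflects how often participants produced it.  Output is SVG by
default (text-based, hence diffable); PNG works via the file extension.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import SchemaError, StateError, UsageError
from .study import AssociationStudy

logger = logging.getLogger(__name__)


def _size_scale(freq: pd.Series, lo: float, hi: float) -> pd.Series:
    """Monotone non-decreasing map from frequency to size (ties equal)."""
    f = freq.astype(float)
    span = f.max() - f.min()
    if span == 0:
        return pd.Series(np.full(len(f), (lo + hi) / 2), index=f.index)
    scaled = (np.log1p(f) - np.log1p(f.min())) / (np.log1p(f.max()) - np.log1p(f.min()))
    return lo + scaled * (hi - lo)


def _plot_table(study: AssociationStudy) -> pd.DataFrame:
    if study.targets is None:
        raise StateError("targets have not been set")
    table = study.targets.copy()
    if "frequency" not in table.columns:
        raise StateError("no frequency column; call count_targets first")
    return table


def plot_embedding_map(
    study: AssociationStudy,
    path: str | Path,
    color_by: str | None = "cluster",
    min_frequency: int = 0,
    figsize: tuple[float, float] = (10.0, 8.0),
) -> Path:
    """Scatter targets on their 2-D projected embedding with text labels.

    Targets below ``min_frequency`` are omitted; sizes follow frequency;
    colors are keyed to the levels of ``color_by`` when given.
    """
    if study.embedding is None:
        raise StateError("no embedding present")
    if study.embedding.n_dim != 2:
        raise StateError(
            f"embedding is {study.embedding.n_dim}-dimensional; project to 2 "
            "dimensions first (project_embedding)"
        )
    table = _plot_table(study)
    if color_by is not None and color_by not in table.columns:
        raise SchemaError(f"targets table has no column {color_by!r}")
    coords = study.embedding.to_frame()
    coords.columns = ["x", "y"]
    table = table.merge(coords, left_on="target", right_index=True, how="inner")
    table = table[table["frequency"] >= min_frequency]

    fig, ax = plt.subplots(figsize=figsize)
    if len(table):
        sizes = _size_scale(table["frequency"], 10.0, 300.0)
        fonts = _size_scale(table["frequency"], 5.0, 16.0)
        if color_by is not None:
            levels = sorted(table[color_by].dropna().unique(), key=str)
            cmap = plt.get_cmap("tab10")
            palette = {lev: cmap(i % 10) for i, lev in enumerate(levels)}
            colors = [palette.get(v, (0.5, 0.5, 0.5, 1.0)) for v in table[color_by]]
        else:
            colors = ["#1f77b4"] * len(table)
        ax.scatter(table["x"], table["y"], s=sizes, c=colors, alpha=0.6, lw=0)
        for (_, row), fs, col in zip(table.iterrows(), fonts, colors):
            ax.annotate(
                row["target"], (row["x"], row["y"]), fontsize=fs, color=col,
                xytext=(2, 2), textcoords="offset points",
            )
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def _spiral_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic Archimedean spiral: earlier (larger) words more central."""
    theta0 = rng.uniform(0, 2 * math.pi)
    pts = []
    for i in range(n):
        r = 0.06 * math.sqrt(i)
        theta = theta0 + i * 2.399963  # golden angle
        pts.append((0.5 + r * math.cos(theta), 0.5 + r * math.sin(theta)))
    return np.asarray(pts)


def plot_wordclouds(
    study: AssociationStudy,
    path: str | Path,
    facet_by: str = "cluster",
    color_by: str | None = None,
    max_words: int = 40,
    seed: int = 0,
    panel_size: float = 3.2,
) -> Path:
    """One word-cloud panel per level of ``facet_by``.

    Words are placed on a golden-angle spiral in descending frequency
    order (frequent words central and large); placement is seeded, so
    identical inputs render identical files.
    """
    table = _plot_table(study)
    if facet_by not in table.columns:
        raise UsageError(f"targets table has no column {facet_by!r}")
    if color_by is not None and color_by not in table.columns:
        raise UsageError(f"targets table has no column {color_by!r}")
    levels = sorted(table[facet_by].dropna().unique(), key=str)
    if not levels:
        raise UsageError(f"column {facet_by!r} has no non-missing levels")
    ncol = min(3, len(levels))
    nrow = math.ceil(len(levels) / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(panel_size * ncol, panel_size * nrow), squeeze=False
    )
    rng = np.random.default_rng(seed)
    cmap = plt.get_cmap("tab10")
    if color_by is not None:
        color_levels = sorted(table[color_by].dropna().unique(), key=str)
        palette = {lev: cmap(i % 10) for i, lev in enumerate(color_levels)}
    for idx, level in enumerate(levels):
        ax = axes[idx // ncol][idx % ncol]
        chunk = (
            table[table[facet_by] == level]
            .sort_values(["frequency", "target"], ascending=[False, True])
            .head(max_words)
        )
        fonts = _size_scale(chunk["frequency"], 6.0, 22.0)
        positions = _spiral_positions(len(chunk), rng)
        for (x, y), (_, row), fs in zip(positions, chunk.iterrows(), fonts):
            if color_by is not None:
                color = palette.get(row[color_by], (0.5, 0.5, 0.5, 1.0))
            else:
                color = cmap(idx % 10)
            ax.text(x, y, row["target"], fontsize=fs, ha="center", va="center",
                    color=color)
        ax.set_title(f"{facet_by} = {level}")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.axis("off")
    for idx in range(len(levels), nrow * ncol):
        axes[idx // ncol][idx % ncol].axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
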