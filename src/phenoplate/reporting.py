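"""Output generation: outlined images, spreadsheet export, plate heat maps,
histograms, scatter plots with a sliding-window trend, and manual-count
summaries.

Numeric artifacts (tables, heat-map grids, trend series) are produced as
plain arrays/DataFrames alongside the figures, so downstream code and tests
work with the numbers rather than rendered pixels; Excel exports always get a
CSV mirror.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .data import LabelMatrix, PlateLayout, parse_well_name
from .features import inner_boundary
from .training import TrainingSession
from .vectors import VectorValue

__all__ = [
    "OutlineSpec",
    "compose_background",
    "render_outlined_image",
    "export_tables",
    "plate_heatmap",
    "histogram",
    "scatter_trend",
    "manual_count_summary",
]


@dataclass(frozen=True)
class OutlineSpec:
    """Ordered outline layers: (vector, RGB color in [0,1]); the first layer
    whose vector flags an object wins (so e.g. "infected mitotic" can take
    precedence over plain "infected"). Non-flagged objects stay unoutlined."""

    layers: tuple[tuple[VectorValue, tuple[float, float, float]], ...]
    line_width: int = 1

    def __post_init__(self) -> None:
        if self.line_width < 1:
            raise ValueError("line_width must be >= 1")
        colors = [c for _, c in self.layers]
        if len(colors) != len(set(colors)):
            raise ValueError("outline colors must be distinct")
        types = {v.parent_type for v, _ in self.layers}
        if len(types) > 1:
            raise ValueError("all outline layers must share one parent type")


def compose_background(
    channels: Mapping[str, np.ndarray],
    channel_colors: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Compose up to 3 grayscale channels into an RGB image with a
    per-channel min-max stretch. ``channel_colors`` maps channel name to one
    of 'r', 'g', 'b' (default: assignment in name order)."""
    names = list(channels)
    if not 1 <= len(names) <= 3:
        raise ValueError("1 to 3 channels supported")
    if channel_colors is None:
        channel_colors = dict(zip(names, "rgb"))
    shape = next(iter(channels.values())).shape
    rgb = np.zeros((*shape, 3), dtype=float)
    slot = {"r": 0, "g": 1, "b": 2}
    for name in names:
        img = np.asarray(channels[name], dtype=float)
        lo, hi = float(img.min()), float(img.max())
        stretched = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        rgb[..., slot[channel_colors[name]]] = stretched
    return rgb


def render_outlined_image(
    channels: Mapping[str, np.ndarray],
    labelmatrix: LabelMatrix,
    spec: OutlineSpec,
    channel_colors: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Project vectors onto the image: the inner 1-px boundary of every
    flagged object (thickened to ``line_width`` inside the object) is painted
    in the color of the first layer that flags it."""
    rgb = compose_background(channels, channel_colors)
    lw_foot = disk(spec.line_width - 1) if spec.line_width > 1 else None
    flagged_color: dict[int, tuple[float, float, float]] = {}
    for vec, color in spec.layers:
        for oid, f in zip(vec.ids, vec.flags):
            if f and int(oid) not in flagged_color:
                flagged_color[int(oid)] = color
    for oid, color in flagged_color.items():
        boundary = inner_boundary(labelmatrix.pixels, oid)
        if lw_foot is not None:
            boundary = binary_dilation(boundary, lw_foot) & labelmatrix.mask(oid)
        rgb[boundary] = color
    return rgb


def export_tables(
    image_values: pd.DataFrame | None,
    well_values: pd.DataFrame | None,
    plate_values: pd.DataFrame | None,
    outdir: str | Path,
    stem: str = "variables",
) -> dict[str, Path]:
    """Write image/well/plate variable tables to one spreadsheet (one sheet
    per level) plus CSV mirrors. Wells are ordered row-major (A01, A02, ...);
    missing values are left as empty cells. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheets = {
        "image": image_values,
        "well": well_values,
        "plate": plate_values,
    }
    written: dict[str, Path] = {}
    xlsx = outdir / f"{stem}.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for name, df in sheets.items():
            if df is None:
                continue
            if name == "well" and "well" in df.columns:
                order = df["well"].map(
                    lambda w: (parse_well_name(w).row, parse_well_name(w).col)
                )
                df = df.iloc[np.argsort(order.to_numpy(), kind="stable")]
            df.to_excel(writer, sheet_name=name, index=False)
            csv = outdir / f"{stem}_{name}.csv"
            # %.17g guarantees float64 values survive the round trip exactly
            df.to_csv(csv, index=False, float_format="%.17g")
            written[name] = csv
    written["xlsx"] = xlsx
    return written


def plate_heatmap(
    well_values: Mapping[str, float],
    layout: PlateLayout,
    title: str = "",
    cmap: str = "viridis",
) -> tuple[plt.Figure, np.ndarray]:
    """Heat map of a well variable over the plate.

    Returns the figure and the nrows x ncols value grid (NaN for missing
    wells, which render distinctly).
    """
    grid = np.full((layout.nrows, layout.ncols), np.nan)
    for name, value in well_values.items():
        addr = parse_well_name(name, layout)
        grid[addr.row, addr.col] = value
    fig, ax = plt.subplots(figsize=(layout.ncols * 0.5 + 1.5, layout.nrows * 0.5 + 1))
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("lightgrey")
    im = ax.imshow(np.ma.masked_invalid(grid), cmap=cm)
    ax.set_xticks(range(layout.ncols), [f"{c + 1:02d}" for c in range(layout.ncols)])
    ax.set_yticks(range(layout.nrows), [chr(ord("A") + r) for r in range(layout.nrows)])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return fig, grid


def histogram(values: Sequence[float], bins: int = 20, title: str = "") -> plt.Figure:
    vals = np.asarray(values, dtype=float)
    fig, ax = plt.subplots()
    ax.hist(vals[~np.isnan(vals)], bins=bins)
    ax.set_title(title)
    return fig


def scatter_trend(
    x: Sequence[float],
    y: Sequence[float],
    window: int,
    title: str = "",
) -> tuple[plt.Figure, np.ndarray]:
    """Scatter plot with a sliding-window trend.

    Points are sorted by x; trend point i is the (mean x, mean y) of ranks
    i..i+window-1 (step 1). Returns the figure and the (n-window+1, 2) trend
    series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    kernel = np.ones(window) / window
    tx = np.convolve(xs, kernel, mode="valid")
    ty = np.convolve(ys, kernel, mode="valid")
    trend = np.column_stack([tx, ty])
    fig, ax = plt.subplots()
    ax.scatter(x, y, s=15, alpha=0.7)
    ax.plot(tx, ty, "o-", color="red", mfc="none", label=f"trend (window {window})")
    ax.legend()
    ax.set_title(title)
    return fig, trend


def manual_count_summary(session: TrainingSession) -> pd.DataFrame:
    """Per-well counts of the user's own labels, one column per class
    (wells without labels are omitted)."""
    if not session.labels:
        raise ValueError("session holds no labels")
    rows = [
        {"plate": r.plate, "well": r.well, "class": c}
        for r, c in session.labels.items()
    ]
    df = pd.DataFrame(rows)
    pivot = (
        df.groupby(["plate", "well", "class"]).size().unstack(fill_value=0).reset_index()
    )
    pivot.columns.name = None
    return pivot
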