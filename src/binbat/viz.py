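"""Bin-plot and cohort visualisation.

The bin plot renders the gridded marker plane with each bin coloured by a
chosen statistic on a blue-to-red scale normalised per sample (minimum
blue, maximum red), below-cutoff bins grey, threshold cross-hairs, the
four quadrant frequencies printed in black and the z-positive percentage
of the target (basophil) quadrant printed in red.  Violin summaries trim
a configurable percentage of outliers (half per tail, nearest-rank
bounds) and mark the median with a solid line and the quartiles with
dashed lines.  SVG output is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .binning import BinStatistic, BinStatsTable, QuadrantStats, bin_color_scale
from .calibration import nearest_rank_percentile
from .errors import EmptySampleError

matplotlib.rcParams["svg.hashsalt"] = "binbat"


@dataclass(frozen=True)
class PlotStyle:
    colormap: str = "coolwarm"  # blue -> red
    below_cutoff_color: str = "0.75"
    quadrant_label_color: str = "black"
    target_zpos_label_color: str = "red"
    warning_glyphs: Mapping[str, str] = field(
        default_factory=lambda: {"WARNING": "(!)", "BLOCKING": "(!!)"}
    )


def _save(fig, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    # fixed metadata so repeated renders are byte-identical
    fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)
    return out


def bin_plot_axes(
    ax,
    stats: BinStatsTable,
    quad: QuadrantStats,
    statistic: BinStatistic = BinStatistic.FREQ,
    style: PlotStyle = PlotStyle(),
    qc_messages: Sequence[str] = (),
    title: str | None = None,
) -> None:
    colors = bin_color_scale(stats, statistic)
    grid = stats.grid
    w = grid.bin_width
    ix = stats.table.index.get_level_values("ix").to_numpy()
    iy = stats.table.index.get_level_values("iy").to_numpy()
    img = np.full((iy.max() - iy.min() + 1, ix.max() - ix.min() + 1), np.nan)
    img[iy - iy.min(), ix - ix.min()] = colors.to_numpy()
    cmap = plt.get_cmap(style.colormap).copy()
    cmap.set_bad(style.below_cutoff_color)
    x0 = grid.origin[0] + ix.min() * w
    y0 = grid.origin[1] + iy.min() * w
    extent = (x0, x0 + img.shape[1] * w, y0, y0 + img.shape[0] * w)
    ax.imshow(img, origin="lower", extent=extent, aspect="auto",
              cmap=cmap, vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.axvline(grid.x_threshold, color="black", lw=0.8)
    ax.axhline(grid.y_threshold, color="black", lw=0.8)

    # black quadrant frequencies in the corners
    xs = {"L": extent[0], "R": extent[1]}
    ys = {"U": extent[3], "L": extent[2]}
    align = {"L": ("left", 0.02), "R": ("right", -0.02)}
    for q, freq in quad.q_freq.items():
        ha, dx = align[q[1]]
        va = "top" if q[0] == "U" else "bottom"
        dy = -0.02 if q[0] == "U" else 0.02
        span_x, span_y = extent[1] - extent[0], extent[3] - extent[2]
        ax.text(xs[q[1]] + dx * span_x, ys[q[0]] + dy * span_y,
                f"{freq:.2f}", color=style.quadrant_label_color,
                ha=ha, va=va, fontsize=8)
    if quad.zpos_pct_target is not None:
        tq = quad.target_quadrant.value
        ha, dx = align[tq[1]]
        va = "top" if tq[0] == "U" else "bottom"
        dy = -0.10 if tq[0] == "U" else 0.10
        span_x, span_y = extent[1] - extent[0], extent[3] - extent[2]
        ax.text(xs[tq[1]] + dx * span_x, ys[tq[0]] + dy * span_y,
                f"{quad.zpos_pct_target:.2f}",
                color=style.target_zpos_label_color, ha=ha, va=va, fontsize=9)
    for k, msg in enumerate(qc_messages):
        glyph = style.warning_glyphs.get("WARNING", "(!)")
        ax.text(0.01, 0.01 + 0.06 * k, f"{glyph} {msg}", transform=ax.transAxes,
                fontsize=6, color="darkorange", va="bottom")
    col = stats.table.loc[~stats.table["below_cutoff"],
                          {"DENSITY": "density", "FREQ": "freq_zpos",
                           "MSI": "msi_all", "MSI_POS": "msi_pos"}[BinStatistic(statistic).value]]
    ax.set_xlabel(f"{grid.x_marker} (transformed)")
    ax.set_ylabel(f"{grid.y_marker} (transformed)")
    label = BinStatistic(statistic).value
    ax.set_title(title or f"{stats.z_marker} {label} "
                          f"[min {np.nanmin(col):.3g}, max {np.nanmax(col):.3g}]",
                 fontsize=9)


def render_bin_plot(
    stats: BinStatsTable,
    quad: QuadrantStats,
    out: str | Path,
    statistic: BinStatistic = BinStatistic.FREQ,
    style: PlotStyle = PlotStyle(),
    qc_messages: Sequence[str] = (),
    title: str | None = None,
) -> Path:
    fig, ax = plt.subplots(figsize=(4.2, 4.0), dpi=100)
    try:
        bin_plot_axes(ax, stats, quad, statistic, style, qc_messages, title)
    except EmptySampleError:
        plt.close(fig)
        raise
    fig.tight_layout()
    return _save(fig, out)


def render_compilation(
    panels: Sequence[tuple[BinStatsTable, QuadrantStats, str]],
    out: str | Path,
    statistic: BinStatistic = BinStatistic.FREQ,
    style: PlotStyle = PlotStyle(),
) -> Path:
    """Multi-panel bin-plot page for one experiment."""
    n = len(panels)
    if n == 0:
        raise ValueError("no panels to render")
    ncol = min(3, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 4.0 * nrow), dpi=100,
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, (stats, quad, title) in zip(axes.ravel(), panels):
        ax.set_axis_on()
        bin_plot_axes(ax, stats, quad, statistic, style, title=title)
    fig.tight_layout()
    return _save(fig, out)


def trim_for_violin(values: np.ndarray, trim_pct: float = 3.0) -> np.ndarray:
    """Symmetric outlier trim: keep values within the nearest-rank
    [trim/2, 100 - trim/2] percentile bounds."""
    v = np.asarray(values, dtype=float)
    lo = nearest_rank_percentile(v, trim_pct / 2.0)
    hi = nearest_rank_percentile(v, 100.0 - trim_pct / 2.0)
    return v[(v >= lo) & (v <= hi)]


def render_violin(
    values_by_group: Mapping[str, Sequence[float]],
    out: str | Path,
    trim_pct: float = 3.0,
) -> Path:
    """Violin summary per group with the outlier trim applied; the median
    is a solid line, the 25%/75% percentiles dashed lines."""
    groups = list(values_by_group)
    data = []
    for g in groups:
        v = np.asarray(values_by_group[g], dtype=float)
        if len(v) < 10:
            raise ValueError(f"group {g!r} needs >= 10 values, got {len(v)}")
        data.append(trim_for_violin(v, trim_pct))
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.6), dpi=100)
    parts = ax.violinplot(data, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    for i, v in enumerate(data, start=1):
        med = float(np.median(v))
        q1 = nearest_rank_percentile(v, 25.0)
        q3 = nearest_rank_percentile(v, 75.0)
        ax.hlines(med, i - 0.2, i + 0.2, color="black", lw=1.4)
        ax.hlines([q1, q3], i - 0.2, i + 0.2, color="black", lw=0.9, linestyle="--")
    ax.set_xticks(range(1, len(groups) + 1), groups)
    fig.tight_layout()
    return _save(fig, out)
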