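"""The bin-based (PRI-style) core: grid the transformed x/y marker plane
and compute per-bin and per-quadrant statistics of a third (z) marker.

Each event falls into exactly one half-open square bin
``[low, low + w) x [low, low + w)``.  Per bin we report the event count,
the density (fraction of all gated events), the percentage of events
whose z value lies strictly above the z threshold (``freq_zpos``), the
mean z signal intensity over all bin events (MSI) and over only the
z-positive events (MSI+, absent when the bin has none).  Bins with fewer
than ``min_cells_per_bin`` events are flagged and excluded from colour
scaling.  Quadrants are defined by the x/y thresholds: x below threshold
is "left", y at or above threshold is "upper".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptySampleError, TransformStateError
from .events import EventTable

DEFAULT_BIN_WIDTH = 0.2
DEFAULT_MIN_CELLS_PER_BIN = 10


class Quadrant(str, enum.Enum):
    UL = "UL"
    UR = "UR"
    LL = "LL"
    LR = "LR"


class BinStatistic(str, enum.Enum):
    DENSITY = "DENSITY"
    FREQ = "FREQ"
    MSI = "MSI"
    MSI_POS = "MSI_POS"


_STAT_COLUMN = {
    BinStatistic.DENSITY: "density",
    BinStatistic.FREQ: "freq_zpos",
    BinStatistic.MSI: "msi_all",
    BinStatistic.MSI_POS: "msi_pos",
}


def snap_to_grid(value: float, origin: float, bin_width: float) -> float:
    """Snap a threshold onto the nearest grid line so bin and quadrant
    boundaries coincide."""
    return origin + round((value - origin) / bin_width) * bin_width


@dataclass(frozen=True)
class BinGrid:
    x_marker: str
    y_marker: str
    bin_width: float = DEFAULT_BIN_WIDTH
    x_threshold: float = 0.0
    y_threshold: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        object.__setattr__(
            self, "x_threshold",
            snap_to_grid(self.x_threshold, self.origin[0], self.bin_width),
        )
        object.__setattr__(
            self, "y_threshold",
            snap_to_grid(self.y_threshold, self.origin[1], self.bin_width),
        )

    def with_thresholds(self, thr_x: float, thr_y: float) -> "BinGrid":
        return BinGrid(self.x_marker, self.y_marker, self.bin_width, thr_x, thr_y, self.origin)


@dataclass
class BinStatsTable:
    """Per-bin statistics, indexed by integer grid coordinates (ix, iy)."""

    table: pd.DataFrame  # columns: n_events, density, freq_zpos, msi_all, msi_pos, below_cutoff
    grid: BinGrid
    z_marker: str
    z_threshold: float
    n_gated: int
    min_cells_per_bin: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)


@dataclass
class QuadrantStats:
    q_freq: Mapping[str, float]  # % of gated events per quadrant
    target_quadrant: Quadrant
    zpos_pct_target: float | None  # the "red percentage"; None if quadrant empty
    zpos_count: int
    n_target: int = 0
    warnings: list[str] = field(default_factory=list)


def _require_transformed(table: EventTable, marker: str) -> np.ndarray:
    if not table.marker_transformed(marker):
        raise TransformStateError(f"marker {marker!r} must be transformed before binning")
    return table.marker_values(marker)


def assign_bins(table: EventTable, grid: BinGrid) -> np.ndarray:
    """Integer (ix, iy) bin index per event; half-open [low, high) bins."""
    x = _require_transformed(table, grid.x_marker)
    y = _require_transformed(table, grid.y_marker)
    ix = np.floor((x - grid.origin[0]) / grid.bin_width).astype(np.int64)
    iy = np.floor((y - grid.origin[1]) / grid.bin_width).astype(np.int64)
    return np.column_stack([ix, iy])


def bin_statistics(
    table: EventTable,
    grid: BinGrid,
    z_marker: str,
    z_threshold: float,
    min_cells_per_bin: int = DEFAULT_MIN_CELLS_PER_BIN,
) -> BinStatsTable:
    if table.n_events == 0:
        raise EmptySampleError("no gated events to bin")
    if min_cells_per_bin < 1:
        raise ValueError("min_cells_per_bin must be >= 1")
    z = _require_transformed(table, z_marker)
    idx = assign_bins(table, grid)
    zpos = z > z_threshold  # positivity is strictly above the threshold

    df = pd.DataFrame({"ix": idx[:, 0], "iy": idx[:, 1], "z": z, "zpos": zpos})
    grouped = df.groupby(["ix", "iy"], sort=True)
    n = grouped.size().rename("n_events")
    msi_all = grouped["z"].mean().rename("msi_all")
    npos = grouped["zpos"].sum()
    zsum_pos = df[df.zpos].groupby(["ix", "iy"])["z"].sum()
    out = pd.concat([n, msi_all], axis=1)
    out["freq_zpos"] = 100.0 * npos / out["n_events"]
    out["msi_pos"] = (zsum_pos / npos).reindex(out.index)  # NaN where npos == 0
    out["density"] = out["n_events"] / table.n_events
    out["below_cutoff"] = out["n_events"] < min_cells_per_bin
    out = out[["n_events", "density", "freq_zpos", "msi_all", "msi_pos", "below_cutoff"]]
    return BinStatsTable(
        table=out,
        grid=grid,
        z_marker=z_marker,
        z_threshold=z_threshold,
        n_gated=table.n_events,
        min_cells_per_bin=min_cells_per_bin,
    )


def quadrant_of(x: np.ndarray, y: np.ndarray, thr_x: float, thr_y: float) -> np.ndarray:
    """Quadrant label per event: x < thr_x is left, y >= thr_y is upper."""
    left = x < thr_x
    upper = y >= thr_y
    labels = np.empty(x.shape, dtype="<U2")
    labels[left & upper] = Quadrant.UL.value
    labels[~left & upper] = Quadrant.UR.value
    labels[left & ~upper] = Quadrant.LL.value
    labels[~left & ~upper] = Quadrant.LR.value
    return labels


def quadrant_statistics(
    table: EventTable,
    grid: BinGrid,
    z_marker: str,
    z_threshold: float,
    target_quadrant: Quadrant = Quadrant.UL,
) -> QuadrantStats:
    if table.n_events == 0:
        raise EmptySampleError("no gated events")
    x = _require_transformed(table, grid.x_marker)
    y = _require_transformed(table, grid.y_marker)
    z = _require_transformed(table, z_marker)
    target_quadrant = Quadrant(target_quadrant)

    labels = quadrant_of(x, y, grid.x_threshold, grid.y_threshold)
    q_freq = {
        q.value: 100.0 * float(np.count_nonzero(labels == q.value)) / table.n_events
        for q in Quadrant
    }
    in_target = labels == target_quadrant.value
    n_target = int(np.count_nonzero(in_target))
    warnings: list[str] = []
    if n_target == 0:
        warnings.append(f"target quadrant {target_quadrant.value} is empty")
        zpos_pct = None
        zpos_count = 0
    else:
        zpos_count = int(np.count_nonzero(z[in_target] > z_threshold))
        zpos_pct = 100.0 * zpos_count / n_target
    return QuadrantStats(
        q_freq=q_freq,
        target_quadrant=target_quadrant,
        zpos_pct_target=zpos_pct,
        zpos_count=zpos_count,
        n_target=n_target,
        warnings=warnings,
    )


def bin_color_scale(stats: BinStatsTable, statistic: BinStatistic) -> pd.Series:
    """Min-max normalise a bin statistic to [0, 1] over non-flagged bins.

    Flagged (below-cutoff) bins and bins where the statistic is undefined
    get NaN — rendered grey, never coloured.  A flat statistic maps every
    bin to 0.5 (documented degenerate convention).
    """
    statistic = BinStatistic(statistic)
    col = stats.table[_STAT_COLUMN[statistic]]
    ok = ~stats.table["below_cutoff"] & col.notna()
    if not ok.any():
        raise EmptySampleError("every bin is below the cell-count cutoff")
    lo, hi = float(col[ok].min()), float(col[ok].max())
    colors = pd.Series(np.nan, index=stats.table.index, name="color")
    if hi > lo:
        colors[ok] = (col[ok] - lo) / (hi - lo)
    else:
        colors[ok] = 0.5
    return colors
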