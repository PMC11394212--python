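"""Automated threshold placement for basophil identification and
activation readout.

The axis thresholds (side scatter and FcεRIα) are found once per donor on
the unstimulated sample by a deterministic grid search over candidate
quantile pairs: a candidate is feasible when the upper-left (basophil)
quadrant holds a plausible basophil-sized fraction of events and is
CD32-pure at a provisional CD32 cut; among feasible candidates the one
with the highest CD32 purity wins, with purity compared at a coarse
resolution so near-ties resolve toward larger basophil yield.

The z-marker thresholds follow the calibration conventions: the CD63
threshold is placed so that a target percentage (default 1%) of the
unstimulated basophils count as positive, and the CD32 threshold so that
a target percentage (default 70%, the red-percentage rule) are positive.
Quantiles are nearest-rank and positivity is strictly above the
threshold, which makes both rules exact and bit-reproducible on the
empirical distribution.  The resulting :class:`ThresholdSet` is frozen
and applied verbatim to every other sample of the donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .binning import DEFAULT_BIN_WIDTH, BinGrid, Quadrant, quadrant_of, snap_to_grid
from .errors import CalibrationError, InsufficientEventsError
from .events import EventTable

#: Purity comparison resolution (percentage points) in the axis search:
#: candidates whose UL CD32+ fractions differ by less than this tie, and
#: the tie-breaks (larger UL count, then lower FcεRIα threshold) apply.
PURITY_RESOLUTION_PP = 0.5


@dataclass(frozen=True)
class CalibrationConfig:
    cd63_target_pct: float = 1.0
    cd32_target_pct: float = 70.0
    cd32_purity_min: float = 70.0  # % CD32+ required in UL during axis search
    baso_freq_bounds: tuple[float, float] = (0.05, 3.0)  # % of gated events
    fcer1a_quantile_grid: tuple[float, ...] = (
        0.990, 0.992, 0.994, 0.995, 0.996, 0.997, 0.998,
    )
    ssc_quantile_grid: tuple[float, ...] = (
        0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
    )
    cd32_provisional_quantile: float = 0.40
    bin_width: float = DEFAULT_BIN_WIDTH
    grid_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("cd63_target_pct", "cd32_target_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        lo, hi = self.baso_freq_bounds
        if not lo < hi:
            raise ValueError("baso_freq_bounds must be ordered")


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated cut points, frozen after calibration on the unstimulated
    sample and reused verbatim on all other samples of the donor."""

    thr_ssc: float
    thr_fcer1a: float
    thr_cd63: float
    thr_cd32: float
    calibrated_on: str
    target_quadrant: Quadrant = Quadrant.UL

    def __post_init__(self) -> None:
        for name in ("thr_ssc", "thr_fcer1a", "thr_cd63", "thr_cd32"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        object.__setattr__(self, "target_quadrant", Quadrant(self.target_quadrant))

    def grid(self, x_marker: str = "SSC", y_marker: str = "FCER1A",
             bin_width: float = DEFAULT_BIN_WIDTH,
             origin: tuple[float, float] = (0.0, 0.0)) -> BinGrid:
        return BinGrid(x_marker, y_marker, bin_width, self.thr_ssc, self.thr_fcer1a, origin)

    def to_dict(self) -> dict:
        return {
            "thr_ssc": self.thr_ssc,
            "thr_fcer1a": self.thr_fcer1a,
            "thr_cd63": self.thr_cd63,
            "thr_cd32": self.thr_cd32,
            "calibrated_on": self.calibrated_on,
            "target_quadrant": self.target_quadrant.value,
        }

    @classmethod
    def from_dict(cls, d) -> "ThresholdSet":
        return cls(
            thr_ssc=d["thr_ssc"], thr_fcer1a=d["thr_fcer1a"],
            thr_cd63=d["thr_cd63"], thr_cd32=d["thr_cd32"],
            calibrated_on=d["calibrated_on"],
            target_quadrant=Quadrant(d["target_quadrant"]),
        )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank q-th percentile: the k-th smallest value with
    k = ceil(q/100 * n) (k at least 1)."""
    values = np.sort(np.asarray(values, dtype=np.float64))
    n = len(values)
    if n == 0:
        raise ValueError("empty input")
    k = max(1, int(np.ceil(q / 100.0 * n)))
    return float(values[min(k, n) - 1])


def find_axis_thresholds(
    unstim: EventTable, cfg: CalibrationConfig = CalibrationConfig()
) -> tuple[float, float]:
    """Grid-search the (SSC, FcεRIα) threshold pair on the unstimulated
    sample, using CD32 purity of the upper-left quadrant as the guide."""
    ssc = unstim.marker_values("SSC")
    fcer1a = unstim.marker_values("FCER1A")
    cd32 = unstim.marker_values("CD32")
    n = unstim.n_events
    if n == 0:
        raise CalibrationError("no events to calibrate on")
    cd32_cut = nearest_rank_percentile(cd32, 100.0 * cfg.cd32_provisional_quantile)
    lo, hi = cfg.baso_freq_bounds

    best: tuple | None = None  # sort key (all to maximise)
    best_pair: tuple[float, float] | None = None
    for q_ssc in cfg.ssc_quantile_grid:
        thr_ssc = snap_to_grid(
            nearest_rank_percentile(ssc, 100.0 * q_ssc), cfg.grid_origin[0], cfg.bin_width
        )
        for q_fc in cfg.fcer1a_quantile_grid:
            thr_fc = snap_to_grid(
                nearest_rank_percentile(fcer1a, 100.0 * q_fc),
                cfg.grid_origin[1], cfg.bin_width,
            )
            in_ul = (ssc < thr_ssc) & (fcer1a >= thr_fc)
            n_ul = int(np.count_nonzero(in_ul))
            frac = 100.0 * n_ul / n
            if not (lo <= frac <= hi) or n_ul == 0:
                continue
            purity = 100.0 * float(np.count_nonzero(cd32[in_ul] > cd32_cut)) / n_ul
            if purity < cfg.cd32_purity_min:
                continue
            purity_rounded = round(purity / PURITY_RESOLUTION_PP)
            key = (purity_rounded, n_ul, -thr_fc, -thr_ssc)
            if best is None or key > best:
                best = key
                best_pair = (thr_ssc, thr_fc)
    if best_pair is None:
        raise CalibrationError(
            "no feasible (SSC, FcεRIα) threshold pair: no candidate quadrant was "
            f"both basophil-sized ({lo}-{hi}% of events) and >= "
            f"{cfg.cd32_purity_min}% CD32+"
        )
    return best_pair


def calibrate_z_threshold(
    z_values: np.ndarray, target_pos_pct: float
) -> tuple[float, list[str]]:
    """Place a z threshold so the realised strictly-above positive fraction
    is the largest achievable value not exceeding ``target_pos_pct``.

    Returns the threshold and any calibration warnings.  Needs at least 10
    events; below 50 a low-count warning is attached.
    """
    z = np.asarray(z_values, dtype=np.float64)
    if len(z) < 10:
        raise InsufficientEventsError(
            f"z-threshold calibration needs >= 10 events, got {len(z)}"
        )
    warnings: list[str] = []
    if len(z) < 50:
        warnings.append(f"only {len(z)} events for z-threshold calibration")
    if np.min(z) == np.max(z):
        warnings.append("degenerate z distribution: all values identical; 0% positive")
        return float(z[0]), warnings
    thr = nearest_rank_percentile(z, 100.0 - target_pos_pct)
    return thr, warnings


class ThresholdApplication(NamedTuple):
    """Raw readout of one frozen ThresholdSet on one sample."""

    n_gated: int
    n_basophils: int
    cd63_pos_pct: float | None  # None when the basophil quadrant is empty
    cd32_pos_pct: float | None
    warnings: tuple[str, ...]


def apply_thresholds(sample: EventTable, ts: ThresholdSet,
                     bin_width: float = DEFAULT_BIN_WIDTH) -> ThresholdApplication:
    """Apply a frozen ThresholdSet: select the basophil quadrant and
    compute CD63+/CD32+ percentages.  No re-fitting happens here."""
    ssc = sample.marker_values("SSC")
    fcer1a = sample.marker_values("FCER1A")
    labels = quadrant_of(ssc, fcer1a, ts.thr_ssc, ts.thr_fcer1a)
    in_target = labels == ts.target_quadrant.value
    n_baso = int(np.count_nonzero(in_target))
    warnings: list[str] = []
    if n_baso == 0:
        warnings.append("basophil quadrant is empty")
        return ThresholdApplication(sample.n_events, 0, None, None, tuple(warnings))
    cd63 = sample.marker_values("CD63")[in_target]
    cd32 = sample.marker_values("CD32")[in_target]
    cd63_pct = 100.0 * float(np.count_nonzero(cd63 > ts.thr_cd63)) / n_baso
    cd32_pct = 100.0 * float(np.count_nonzero(cd32 > ts.thr_cd32)) / n_baso
    return ThresholdApplication(sample.n_events, n_baso, cd63_pct, cd32_pct, tuple(warnings))


def calibrate(
    unstim: EventTable,
    sample_id: str,
    cfg: CalibrationConfig = CalibrationConfig(),
) -> tuple[ThresholdSet, list[str]]:
    """Full calibration on the unstimulated sample: axis thresholds by
    grid search, then the CD63 1%-rule and CD32 red-percentage-rule
    thresholds on the basophil-quadrant events."""
    thr_ssc, thr_fc = find_axis_thresholds(unstim, cfg)
    ssc = unstim.marker_values("SSC")
    fcer1a = unstim.marker_values("FCER1A")
    in_ul = (ssc < thr_ssc) & (fcer1a >= thr_fc)
    cd63 = unstim.marker_values("CD63")[in_ul]
    cd32 = unstim.marker_values("CD32")[in_ul]
    thr_cd63, w63 = calibrate_z_threshold(cd63, cfg.cd63_target_pct)
    thr_cd32, w32 = calibrate_z_threshold(cd32, cfg.cd32_target_pct)
    ts = ThresholdSet(
        thr_ssc=thr_ssc, thr_fcer1a=thr_fc, thr_cd63=thr_cd63, thr_cd32=thr_cd32,
        calibrated_on=sample_id,
    )
    return ts, w63 + w32
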