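"""Pregating: remove doublets, debris and thrombocytes before analysis.

Doublets are excluded with a robust singlet line: FSC-H regressed on
FSC-A by Theil–Sen over a seeded, canonically-ordered subsample; events
whose residual magnitude exceeds ``singlet_band_k`` times the median
absolute deviation (MAD) of residuals are dropped.  Debris and
thrombocytes are excluded by linear FSC-A floors, thrombocytes with the
additional small-AND-low rule (low side scatter).

Pregating is a pure filter: it never modifies values, and the retained
event set is invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EmptySampleError, InsufficientEventsError
from .events import EventTable

_MIN_EVENTS = 50
_FIT_SUBSAMPLE = 2000


@dataclass(frozen=True)
class PregateConfig:
    singlet_band_k: float = 4.0
    #: FSC-A floors in linear units; None derives them from the sample
    #: (debris: 0.25x median FSC-A, thrombocytes: 0.4x median FSC-A).
    fsc_debris_min: float | None = None
    fsc_thrombocyte_min: float | None = None
    eosinophil_exclusion: bool = False
    eos_ssc_quantile: float = 0.985
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.singlet_band_k > 0:
            raise ValueError("singlet_band_k must be > 0")
        if (
            self.fsc_debris_min is not None
            and self.fsc_thrombocyte_min is not None
            and self.fsc_debris_min > self.fsc_thrombocyte_min
        ):
            raise ValueError("fsc_debris_min must be <= fsc_thrombocyte_min")


def _canonical_order(values: np.ndarray) -> np.ndarray:
    """Deterministic row order independent of input ordering."""
    return np.lexsort(values.T[::-1])


def gate_singlets(table: EventTable, cfg: PregateConfig = PregateConfig()) -> EventTable:
    """Keep events near the robust FSC-H ~ FSC-A singlet line."""
    if table.n_events < _MIN_EVENTS:
        raise InsufficientEventsError(
            f"singlet gating needs >= {_MIN_EVENTS} events, got {table.n_events}"
        )
    fsc_a = table.marker_values("FSC_A")
    fsc_h = table.marker_values("FSC_H")

    order = _canonical_order(np.column_stack([fsc_a, fsc_h]))
    rng = np.random.default_rng(cfg.seed)
    if len(order) > _FIT_SUBSAMPLE:
        pick = order[np.sort(rng.choice(len(order), _FIT_SUBSAMPLE, replace=False))]
    else:
        pick = order
    slope, intercept, _, _ = stats.theilslopes(fsc_h[pick], fsc_a[pick])

    resid = fsc_h - (intercept + slope * fsc_a)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid) <= cfg.singlet_band_k * mad
    else:  # collinear input: zero residual band
        keep = np.abs(resid) <= 1e-9 * max(1.0, float(np.abs(fsc_h).max()))
    out = table.subset(keep)
    out.metadata["singlet_retention"] = float(keep.mean())
    return out


def exclude_debris_thrombocytes(
    table: EventTable, cfg: PregateConfig = PregateConfig()
) -> EventTable:
    """Drop small events (debris) and small-and-low events (thrombocytes)."""
    fsc_a = table.marker_values("FSC_A")
    median_fsc = float(np.median(fsc_a))
    debris_min = cfg.fsc_debris_min if cfg.fsc_debris_min is not None else 0.25 * median_fsc
    thromb_min = (
        cfg.fsc_thrombocyte_min if cfg.fsc_thrombocyte_min is not None else 0.4 * median_fsc
    )

    keep = fsc_a >= debris_min
    ssc = table.marker_values("SSC")
    ssc_median = float(np.median(ssc[keep])) if keep.any() else 0.0
    keep &= ~((fsc_a < thromb_min) & (ssc < ssc_median))
    if cfg.eosinophil_exclusion:
        keep &= ssc <= np.quantile(ssc, cfg.eos_ssc_quantile)
    if not keep.any():
        raise EmptySampleError("scatter cutoffs removed every event")
    out = table.subset(keep)
    out.metadata["scatter_retention"] = float(keep.mean())
    return out


def pregate(table: EventTable, cfg: PregateConfig = PregateConfig()) -> EventTable:
    """Full pregating chain: singlets, then debris/thrombocyte exclusion."""
    return exclude_debris_thrombocytes(gate_singlets(table, cfg), cfg)
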