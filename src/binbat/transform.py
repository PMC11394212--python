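"""Intensity transforms: raw instrument units to the quasi-logarithmic
scale on which binning and thresholds operate.

Fluorescence/mass channels get the inverse hyperbolic sine,
``asinh(x / cofactor)`` — linear near zero, logarithmic for large x.
Scatter channels used for linear pregating ratios stay on the identity
scale.  Applying a transform twice is a state error, not a silent no-op.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import TransformStateError
from .events import EventTable

#: Community-convention cofactors: fluorescence ~150, mass cytometry ~5.
DEFAULT_FLUOR_COFACTOR = 150.0
DEFAULT_MASS_COFACTOR = 5.0
#: Side scatter spans decades on modern instruments; a large cofactor keeps
#: the transformed axis commensurate with fluorescence bin widths.
DEFAULT_SSC_COFACTOR = 1000.0


class Method(str, enum.Enum):
    ASINH = "ASINH"
    IDENTITY = "IDENTITY"


@dataclass(frozen=True)
class ChannelTransform:
    method: Method = Method.ASINH
    cofactor: float = DEFAULT_FLUOR_COFACTOR

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.method is Method.ASINH and not self.cofactor > 0:
            raise ValueError("ASINH cofactor must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.method is Method.ASINH:
            return np.arcsinh(np.asarray(x, dtype=np.float64) / self.cofactor)
        return np.asarray(x, dtype=np.float64)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        if self.method is Method.ASINH:
            return np.sinh(np.asarray(y, dtype=np.float64)) * self.cofactor
        return np.asarray(y, dtype=np.float64)


@dataclass(frozen=True)
class TransformSpec:
    """Per-channel transform assignment (physical channel name keyed)."""

    channels: Mapping[str, ChannelTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", dict(self.channels))

    def for_channel(self, name: str) -> ChannelTransform:
        return self.channels.get(name, ChannelTransform(Method.IDENTITY, 1.0))

    @classmethod
    def default_for(cls, table: EventTable) -> "TransformSpec":
        """Identity on FSC, asinh(cofactor 1000) on SSC, asinh(150) elsewhere."""
        if table.channel_map is None:
            raise ValueError("default transform needs a channel map")
        mapping = table.channel_map.mapping
        chans: dict[str, ChannelTransform] = {}
        for marker, chan in mapping.items():
            if marker in ("FSC_A", "FSC_H"):
                chans[chan] = ChannelTransform(Method.IDENTITY, 1.0)
            elif marker == "SSC":
                chans[chan] = ChannelTransform(Method.ASINH, DEFAULT_SSC_COFACTOR)
            else:
                chans[chan] = ChannelTransform(Method.ASINH, DEFAULT_FLUOR_COFACTOR)
        return cls(chans)


def apply_transform(table: EventTable, spec: TransformSpec) -> EventTable:
    """Return a new table with the spec applied to every covered channel.

    Channels absent from the spec are left untouched (and unflagged).
    Re-transforming an already-transformed channel raises
    :class:`TransformStateError` — the scale would silently double-compress.
    """
    values = table.values.copy()
    flags = dict(table.transformed)
    for name, tf in spec.channels.items():
        if name not in table.channel_names:
            continue
        if flags.get(name, False):
            raise TransformStateError(f"channel {name!r} is already transformed")
        j = table.column(name)
        values[:, j] = tf(values[:, j])
        flags[name] = True
    return replace(table, values=values, transformed=flags, metadata=dict(table.metadata))
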