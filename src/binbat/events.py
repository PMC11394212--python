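"""Event-table model: the universal currency of the pipeline.

An :class:`EventTable` is an events x channels matrix of finite, numeric
intensities plus ordered unique channel names, per-channel transformed
flags and free-form side metadata.  A :class:`ChannelMap` binds logical
marker names (``SSC``, ``FCER1A``, ``CD63`` ...) to physical channel
names; a :class:`SampleMeta` records donor and stimulation condition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelResolutionError, ParseError

#: Markers the automated BAT workflow cannot run without.
REQUIRED_MARKERS = ("FSC_A", "FSC_H", "SSC", "FCER1A", "CD63", "CD32")
#: Markers that may be present and are carried through if mapped.
OPTIONAL_MARKERS = ("CD123", "HLA_DR", "CCR3", "CRTH2")


class Condition(str, enum.Enum):
    """Stimulation condition of one BAT tube."""

    UNSTIM = "UNSTIM"
    POS_CTRL = "POS_CTRL"
    ALLERGEN = "ALLERGEN"


@dataclass(frozen=True)
class SampleMeta:
    donor_id: str
    condition: Condition
    allergen_name: str | None = None
    instrument: str | None = None

    def __post_init__(self) -> None:
        cond = Condition(self.condition)
        object.__setattr__(self, "condition", cond)
        if cond is Condition.ALLERGEN and not self.allergen_name:
            raise ValueError("allergen_name required for ALLERGEN condition")
        if cond is not Condition.ALLERGEN and self.allergen_name:
            raise ValueError("allergen_name only allowed for ALLERGEN condition")

    @property
    def sample_id(self) -> str:
        parts = [self.donor_id, self.condition.value]
        if self.allergen_name:
            parts.append(self.allergen_name)
        return "_".join(parts)

    def to_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "condition": self.condition.value,
            "allergen_name": self.allergen_name,
            "instrument": self.instrument,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleMeta":
        return cls(
            donor_id=d["donor_id"],
            condition=Condition(d["condition"]),
            allergen_name=d.get("allergen_name") or None,
            instrument=d.get("instrument") or None,
        )


@dataclass(frozen=True)
class ChannelMap:
    """Logical marker -> physical channel name mapping."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        unknown = set(self.mapping) - set(REQUIRED_MARKERS) - set(OPTIONAL_MARKERS)
        if unknown:
            raise ValueError(f"unknown logical markers: {sorted(unknown)}")

    def channel(self, marker: str) -> str:
        try:
            return self.mapping[marker]
        except KeyError:
            raise ChannelResolutionError(f"marker {marker!r} is not mapped") from None

    def markers(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def validate_against(self, channel_names: Sequence[str], require_all: bool = False) -> None:
        """Check every mapped channel exists; optionally that required markers are mapped."""
        missing = {m: ch for m, ch in self.mapping.items() if ch not in channel_names}
        if missing:
            m, ch = next(iter(missing.items()))
            raise ChannelResolutionError(
                f"marker {m!r} maps to channel {ch!r} which is absent from the data"
            )
        if require_all:
            absent = [m for m in REQUIRED_MARKERS if m not in self.mapping]
            if absent:
                raise ChannelResolutionError(f"required markers not mapped: {absent}")

    @classmethod
    def identity(cls, markers: Iterable[str]) -> "ChannelMap":
        return cls({m: m for m in markers})


@dataclass
class EventTable:
    """Events x channels matrix with channel names and transform state."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    channel_map: ChannelMap | None = None
    transformed: dict[str, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.channel_names))
        self.channel_names = tuple(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParseError("duplicate channel names")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("column count does not match channel_names")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("event values must be finite")
        for name in self.channel_names:
            self.transformed.setdefault(name, False)
        if self.channel_map is not None:
            self.channel_map.validate_against(self.channel_names)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ChannelResolutionError(f"channel {channel!r} not in table") from None

    def marker_values(self, marker: str) -> np.ndarray:
        """Values of a logical marker, resolved through the channel map."""
        if self.channel_map is None:
            raise ChannelResolutionError("event table has no channel map")
        return self.values[:, self.column(self.channel_map.channel(marker))]

    def marker_transformed(self, marker: str) -> bool:
        if self.channel_map is None:
            raise ChannelResolutionError("event table has no channel map")
        return self.transformed[self.channel_map.channel(marker)]

    def subset(self, mask_or_index: np.ndarray) -> "EventTable":
        """Pure row filter; values and transform state are shared conventions."""
        return replace(
            self,
            values=self.values[mask_or_index],
            transformed=dict(self.transformed),
            metadata=dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.channel_names))


def load_csv(path: str | Path, channel_map: ChannelMap | None = None) -> EventTable:
    """Read a plain event table: header of channel names, numeric body."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    raw_names = [c.strip() for c in header.split(",")] if header else []
    if len(set(raw_names)) != len(raw_names):
        raise ParseError(f"{path}: duplicate channel names in header")
    try:
        df = pd.read_csv(path, header=0)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    names = [str(c) for c in df.columns]
    arr = np.empty((len(df), len(names)), dtype=np.float64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r}, row {row}")
        arr[:, j] = numeric.to_numpy(dtype=np.float64)
    if channel_map is not None:
        channel_map.validate_against(names)
    return EventTable(values=arr, channel_names=tuple(names), channel_map=channel_map,
                      metadata={"source": str(path), "format": "csv"})


def write_csv(table: EventTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def load_fcs(path: str | Path, channel_map: ChannelMap | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Raw channel values are kept untransformed; TEXT-segment keywords are
    preserved under ``metadata['fcs_keywords']``.  Compensation is not
    applied: inputs are assumed compensated upstream.
    """
    from ._fcs import read_fcs

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values, names, keywords = read_fcs(path)
    if channel_map is not None:
        channel_map.validate_against(names)
    return EventTable(
        values=values,
        channel_names=tuple(names),
        channel_map=channel_map,
        metadata={"source": str(path), "format": "fcs", "fcs_keywords": keywords},
    )


def write_fcs(table: EventTable, path: str | Path) -> None:
    from ._fcs import write_fcs as _write

    _write(path, table.values, list(table.channel_names))
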