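"""Shared fixtures: small hand-built event tables and cached synthetic
samples (module-expensive generation done once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from binbat import (
    ChannelMap,
    Condition,
    EventTable,
    SyntheticProfile,
    TransformSpec,
    WorkflowConfig,
    apply_transform,
    generate_sample,
)
from binbat.workflow import prepare_sample


def make_table(
    columns: dict[str, np.ndarray],
    transformed: bool = True,
) -> EventTable:
    """Event table with identity marker->channel mapping, optionally marked
    as already on the analysis scale."""
    names = tuple(columns)
    values = np.empty((len(next(iter(columns.values()))), len(names)))
    for j, c in enumerate(names):
        values[:, j] = np.asarray(columns[c], dtype=float)
    from binbat.events import OPTIONAL_MARKERS, REQUIRED_MARKERS

    markers = [c for c in names if c in REQUIRED_MARKERS + OPTIONAL_MARKERS]
    table = EventTable(
        values=values,
        channel_names=names,
        channel_map=ChannelMap.identity(markers) if markers else None,
        transformed={c: transformed for c in names},
    )
    return table


@pytest.fixture(scope="session")
def default_profile() -> SyntheticProfile:
    return SyntheticProfile()


@pytest.fixture(scope="session")
def unstim_sample(default_profile):
    """One seeded unstimulated sample (raw scale) plus ground truth."""
    return generate_sample(default_profile, Condition.UNSTIM, 100_000, seed=1)


@pytest.fixture(scope="session")
def unstim_transformed(unstim_sample):
    table, truth = unstim_sample
    return apply_transform(table, TransformSpec.default_for(table)), truth


@pytest.fixture(scope="session")
def unstim_gated(unstim_sample):
    table, _ = unstim_sample
    return prepare_sample(table, WorkflowConfig())
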