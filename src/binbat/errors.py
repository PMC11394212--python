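"""Exception hierarchy for the binbat pipeline.

Every failure mode a caller may want to branch on gets its own class; all
inherit from :class:`BinBatError` so a CLI can catch the lot.
"""


class BinBatError(Exception):
    """Base class for all binbat errors."""


class ChannelResolutionError(BinBatError):
    """A logical marker could not be resolved to a channel column."""


class ParseError(BinBatError):
    """Malformed input file (FCS, CSV, config, manifest)."""


class TransformStateError(BinBatError):
    """A channel was (re-)transformed in an invalid state."""


class InsufficientEventsError(BinBatError):
    """Too few events for the requested operation."""


class EmptySampleError(BinBatError):
    """An operation removed or received every event."""


class CalibrationError(BinBatError):
    """Automated threshold placement found no feasible candidate."""


class DegenerateDataError(BinBatError):
    """Input data is degenerate for the requested statistic."""


class ConfigError(BinBatError):
    """Invalid configuration or experiment layout."""
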