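"""Exception hierarchy for screen-analysis failures.

All errors derive from :class:`PbscreenError` (a ``ValueError``) so callers
can catch everything from this package with one clause while scripts that
only use a single operation still see a conventional ``ValueError``.
"""


class PbscreenError(ValueError):
    """Base class for all pbscreen errors."""


class InputError(PbscreenError):
    """Malformed input data (bad characters, missing key fields, unsorted arrays)."""


class ParameterError(PbscreenError):
    """Invalid parameter value (negative tolerance, n < 1, zero cohort size)."""


class ConfigurationError(PbscreenError):
    """Inconsistent configuration (insertions on chromosomes without TTAA sites,
    drivers referencing unknown genes, gene demand exceeding genome capacity)."""


class MetadataError(PbscreenError):
    """Conflicting sample metadata (e.g. one sample_id with two tissue labels)."""


class StatisticsError(PbscreenError):
    """A statistic was requested from degenerate data (e.g. an empty null)."""


class DataConsistencyError(PbscreenError):
    """Records that contradict the screen's construct semantics
    (e.g. a splice-donor fusion in antisense orientation)."""
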