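"""Exception hierarchy for specal."""


class SpecalError(Exception):
    """Base class for all specal errors."""


class FormatError(SpecalError):
    """Malformed spectral CSV or header content."""


class UnsupportedFormatError(SpecalError):
    """File uses a declared but unsupported layout (interleave, data type...)."""


class CorruptFileError(SpecalError):
    """Binary payload inconsistent with its header."""


class EmptyRegionError(SpecalError):
    """A pixel mask selects no pixels."""


class DegenerateReferenceError(SpecalError):
    """Scatter-correction reference spectrum has zero variance."""


class DegenerateSampleError(SpecalError):
    """A sample's fitted scatter slope is numerically zero."""


class DisconnectedGraphError(SpecalError):
    """Neighborhood graph has more than one connected component."""


class ConfigError(SpecalError):
    """Invalid pipeline or active-learning configuration."""


class ProtocolError(SpecalError):
    """Active-learning bookkeeping violated (e.g. pool exhausted)."""
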