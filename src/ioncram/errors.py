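"""Exception hierarchy.

All errors raised by this package derive from :class:`IonCramError` so
callers (and the CLI) can catch one type at the boundary.
"""


class IonCramError(Exception):
    """Base class for all ioncram errors."""


class FormatError(IonCramError):
    """Input file or tag does not conform to the expected format."""


class ConsistencyError(IonCramError):
    """Internally inconsistent data handed between pipeline stages."""


class CorruptionError(IonCramError):
    """Archive or compressed stream is damaged or mismatched."""


class ConfigurationError(IonCramError):
    """Unsupported or out-of-range option."""
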