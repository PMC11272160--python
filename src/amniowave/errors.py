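"""Exception hierarchy shared across the pipeline stages."""


class AmniowaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AmniowaveError, ValueError):
    """A configuration object violates its invariants; message names the field."""


class ParseError(AmniowaveError, ValueError):
    """An input file is malformed; message carries file context (line where known)."""


class NormalizationError(AmniowaveError, ValueError):
    """Size-factor estimation is impossible on the given matrix."""
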