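"""Exception types shared across the package."""


class OrigametryError(Exception):
    """Base class for all package errors."""


class ParseError(OrigametryError):
    """A file could not be parsed (message names the offending line/frame)."""


class ValidationError(OrigametryError):
    """Parsed data violates an internal consistency requirement."""


class UnsupportedFormatError(ParseError):
    """The file is a recognizable but unsupported dialect."""


class AnalysisError(OrigametryError):
    """An analysis precondition is not met (degenerate geometry, too few points...)."""
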