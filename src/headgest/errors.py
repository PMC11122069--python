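"""Exception hierarchy shared across the package."""


class HeadgestError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeadgestError, ValueError):
    """A file does not conform to the expected layout (missing columns, duplicate labels...)."""


class ParseError(HeadgestError, ValueError):
    """A cell or field could not be parsed as a number."""


class ConfigError(HeadgestError, ValueError):
    """A configuration object or file violates its invariants."""


class DetectionError(HeadgestError, ValueError):
    """Activity detection was asked to run on an unusable input."""


class PipelineError(HeadgestError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
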