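"""Exception hierarchy shared across the package."""


class SpectraFuseError(Exception):
    """Base class for all package errors."""


class ValidationError(SpectraFuseError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(SpectraFuseError, ValueError):
    """A file could not be parsed under the requested dialect."""


class ParameterError(SpectraFuseError, ValueError):
    """An operation received an out-of-range parameter."""


class PipelineError(SpectraFuseError, RuntimeError):
    """A pipeline stage failed; carries stage context in the message."""
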