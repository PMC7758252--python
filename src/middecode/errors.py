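"""Exception hierarchy shared across the pipeline stages."""


class MiddecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MiddecodeError):
    """A spec/config object is internally inconsistent or unsupported."""


class ValidationError(MiddecodeError):
    """Input data violates a precondition of an operation."""


class IOFormatError(MiddecodeError):
    """A file does not conform to the epoch-container schema."""
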