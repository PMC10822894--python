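"""Exception hierarchy used across the package."""


class DecflowError(Exception):
    """Base class for all package errors."""


class ParameterError(DecflowError, ValueError):
    """A caller-supplied parameter is invalid (bad probability, size, mode...)."""


class DataError(DecflowError, ValueError):
    """Input data violates a contract (labels out of range, missing cells...)."""


class FormatError(DataError):
    """A file could not be parsed; message points at the offending location."""


class StateError(DecflowError, RuntimeError):
    """An operation was called before its prerequisites were established."""
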