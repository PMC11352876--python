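"""Exception hierarchy shared across szdetect modules."""


class SzdetectError(Exception):
    """Base class for all package errors."""


class FormatError(SzdetectError, ValueError):
    """A file or serialized object does not conform to the expected format."""


class ConfigurationError(SzdetectError, ValueError):
    """A configuration object or parameter is invalid for the operation."""


class ConsistencyError(SzdetectError, ValueError):
    """An internally inconsistent object was passed to an operation."""


class DataNotFoundError(SzdetectError, FileNotFoundError):
    """A requested data file or directory does not exist."""
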