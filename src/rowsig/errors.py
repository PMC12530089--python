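"""Exception taxonomy.

Grouped so the CLI can map error families onto distinct process exit codes:
configuration/validation problems, I/O problems, and file-integrity problems
are told apart by their base class.
"""


class RowsigError(Exception):
    """Base class for all rowsig errors."""


class ConfigError(RowsigError):
    """A configuration value is missing, malformed or inconsistent."""


class ValidationError(RowsigError):
    """A record or header violates a format invariant."""


class InvalidCalibrationError(ValidationError):
    """Calibration fields cannot produce a picoampere conversion."""


class SerializationError(ValidationError):
    """A value cannot be represented in the target dialect."""


class ParseError(RowsigError):
    """A text file does not conform to the dialect grammar."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(RowsigError):
    """File contents are internally inconsistent."""


class TruncatedFileError(IntegrityError):
    """A container file ends before its end-of-file marker."""


class CorruptionError(IntegrityError):
    """A container file contains structurally impossible data."""


class CodecError(RowsigError):
    """Base class for signal/record codec failures."""


class CodecRangeError(CodecError):
    """A value does not fit the codec variant's byte budget."""


class MalformedPayloadError(CodecError):
    """A compressed payload is truncated, padded or otherwise invalid."""


class CodecUnavailableError(CodecError):
    """A requested codec backend is not available in this installation."""


class DuplicateReadIDError(IntegrityError):
    """Two records in one file share a read ID."""


class StaleIndexError(IntegrityError):
    """An index sidecar does not match the data file it accompanies."""


class ReadNotFoundError(RowsigError):
    """A requested read ID is absent from the file/index."""


class ConversionError(RowsigError):
    """A lossy field conversion would overflow the target type."""


class SimulationError(RowsigError):
    """Acquisition-simulator failure."""


class RunDirError(SimulationError):
    """Simulator output directory is dirty or unusable."""
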