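"""Structured errors raised across the pipeline.

Pipeline stages distinguish *data failures* (a read that does not pass
trimming or QC — recorded in the outputs, never raised) from *input errors*
(unreadable or malformed files, inconsistent metadata — raised as subclasses
of :class:`BsptraceError`).
"""


class BsptraceError(Exception):
    """Base class for all structured errors raised by this package."""


class AbifError(BsptraceError):
    """The file is missing, truncated, or not an ABIF container."""


class MissingFieldError(AbifError):
    """A required ABIF directory entry is absent.

    The missing tag name is stored in :attr:`field`.
    """

    def __init__(self, field: str, path: str = ""):
        self.field = field
        self.path = path
        super().__init__(f"ABIF file {path!r} is missing required field {field!r}")


class ReferenceFormatError(BsptraceError):
    """The reference FASTA or its coordinate metadata is invalid."""


class NoAlignmentError(BsptraceError):
    """A read could not be aligned to either converted template."""


class ConfigError(BsptraceError):
    """A run configuration file contains unknown or invalid entries."""
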