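"""Exception hierarchy shared by the whole package."""


class IsovizError(Exception):
    """Base class for all package errors."""


class GtfParseError(IsovizError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(IsovizError):
    """Input data violates a structural contract (strand, IDs, overlaps...)."""


class FormatError(IsovizError):
    """Unknown or unsupported file format."""


class ConfigurationError(IsovizError):
    """A user-supplied option is invalid (unknown metric, cap <= 0...)."""


class AssemblyError(IsovizError):
    """Figure fragments disagree (row-order mismatch, missing transcript)."""
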