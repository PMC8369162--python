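"""Exception hierarchy for the package."""


class AophmmError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(AophmmError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceValidationError(AophmmError):
    """Raised when a sequence contains non-standard residue codes."""


class HHMParseError(AophmmError):
    """Raised when a ``.hhm`` profile file cannot be parsed consistently."""


class EncodingError(AophmmError):
    """Raised when one or more inputs violate an encoder precondition."""


class RegistryMismatchError(AophmmError):
    """Raised when feature component names of a table and a model disagree."""


class ExternalToolError(AophmmError):
    """Raised when an external executable or database is missing or fails."""
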