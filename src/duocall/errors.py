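"""Exception hierarchy shared across the package."""


class DuocallError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DuocallError):
    """A file does not conform to its declared format."""


class InputError(DuocallError):
    """Inputs are well-formed but semantically invalid (duplicates, unknown contig, ...)."""


class ConfigError(DuocallError):
    """A configuration value or combination is invalid or infeasible."""


class ReferenceMismatchError(InputError):
    """A variant's REF allele disagrees with the reference sequence."""
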