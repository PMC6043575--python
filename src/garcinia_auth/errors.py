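"""Exception hierarchy shared across the package."""


class GarciniaAuthError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GarciniaAuthError, ValueError):
    """A parameter violates a documented precondition."""


class ConfigurationError(GarciniaAuthError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""


class RangeError(GarciniaAuthError, ValueError):
    """A requested window or index lies outside the data it addresses."""


class InsufficientDataError(GarciniaAuthError, ValueError):
    """Too few points / records to carry out the operation."""


class CannotQuantifyError(GarciniaAuthError, RuntimeError):
    """The internal-reference signal is missing or unusable."""


class ZeroNoiseError(GarciniaAuthError, ZeroDivisionError):
    """Signal-to-noise is undefined because the noise estimate is zero."""


class AlignmentError(GarciniaAuthError, ValueError):
    """Sequences are not comparable (length mismatch, wrong alphabet...)."""


class FastaParseError(GarciniaAuthError, ValueError):
    """A FASTA file violates the expected record conventions."""


class TreeError(GarciniaAuthError, ValueError):
    """A distance matrix or tree cannot support the requested operation."""


class FixtureIntegrityError(GarciniaAuthError, RuntimeError):
    """The embedded study fixtures fail their checksum."""
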