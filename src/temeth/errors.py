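"""Exception hierarchy shared across the package."""


class TemethError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TemethError):
    """Invalid or inconsistent configuration (unknown genotype, key, profile...)."""


class SizingError(TemethError):
    """Planted features do not fit into the requested genome."""


class GFFParseError(TemethError):
    """Malformed GFF3 line; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SpecificityError(TemethError):
    """A primer or flank is not unique in the genome."""


class SiteError(TemethError):
    """A requested coordinate is not a recognition site of the chosen enzyme."""


class CalibrationError(TemethError):
    """Root finding for a hazard multiplier failed or missed its target."""


class UndefinedRatioError(TemethError):
    """Denominator of a requested ratio is zero."""


class NormalizationError(TemethError):
    """No reference-class rows available to normalize against."""
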