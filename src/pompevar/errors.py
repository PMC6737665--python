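"""Exception types shared across the package."""


class PompevarError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(PompevarError, ValueError):
    """A cDNA or protein coordinate is outside the valid range."""


class HgvsParseError(PompevarError, ValueError):
    """An HGVS variant description could not be parsed."""


class UnsupportedVariantError(PompevarError, ValueError):
    """A syntactically valid variant kind this engine does not handle."""


class ReferenceMismatchError(PompevarError, ValueError):
    """Stated reference bases disagree with the supplied coding sequence."""


class ValidationError(PompevarError, ValueError):
    """An input table or model violates a structural invariant."""
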