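"""Exception hierarchy for nirleaf.

All package-specific errors derive from :class:`NirleafError` so callers can
catch everything the workflow may raise with a single except clause.
"""


class NirleafError(Exception):
    """Base class for all nirleaf errors."""


class FormatError(NirleafError):
    """A file does not parse under the declared layout."""


class SpectraValidationError(NirleafError):
    """Spectral or reference values violate a domain invariant."""


class GridMismatchError(NirleafError):
    """Spectra do not share a common wavelength grid, or a model is applied
    to spectra on a different grid."""


class ConfigurationError(NirleafError):
    """A parameter is outside its admissible range."""


class DegenerateInputError(NirleafError):
    """Input has no usable structure (e.g. all rows identical, zero-variance
    response)."""


class DataSizeError(NirleafError):
    """Too few samples for the requested operation."""
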