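"""Exception hierarchy for lipidorder."""


class LipidOrderError(Exception):
    """Base class for all lipidorder errors."""


class SpectrumParseError(LipidOrderError):
    """A spectrum file could not be parsed (malformed row, bad columns)."""


class SpectrumValidationError(LipidOrderError):
    """A spectrum violates an invariant (non-monotone grid, NaN, duplicates)."""


class CoverageError(LipidOrderError):
    """A correction curve or blank does not cover the spectrum's window."""


class WavelengthRangeError(LipidOrderError):
    """A wavelength outside the spectrum's span was requested."""


class FitError(LipidOrderError):
    """The deconvolution could not be set up (bad inputs, not convergence)."""


class DegenerateInputError(LipidOrderError):
    """Input carries no usable signal (e.g. an all-zero spectrum)."""


class SeriesError(LipidOrderError):
    """A dose series is inconsistent (missing control, duplicates, mixed systems)."""


class GeometryError(LipidOrderError):
    """A bilayer frame is unusable for the requested analysis."""
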