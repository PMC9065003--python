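"""Exception hierarchy shared across the package."""


class RamanSaltError(Exception):
    """Base class for all package errors."""


class FormatError(RamanSaltError):
    """A spectral table file is malformed (ragged rows, missing columns)."""


class AxisError(RamanSaltError):
    """A shift axis violates its invariants (non-monotone, wrong length)."""


class AlignmentError(RamanSaltError):
    """Spectra that must share one shift axis do not."""


class MetadataError(RamanSaltError):
    """Sample metadata is missing, duplicated, or inconsistent."""


class ValidationError(RamanSaltError):
    """A container holds values that violate a type invariant (e.g. NaN)."""


class ParameterError(RamanSaltError):
    """An operation received an out-of-contract parameter."""


class NormalizationError(RamanSaltError):
    """A spectrum cannot be normalized (zero Euclidean norm)."""


class ExtrapolationError(RamanSaltError):
    """A resampling grid extends beyond the measured shift range."""


class InputError(RamanSaltError):
    """Operation input is empty or dimensionally inconsistent."""


class FitError(RamanSaltError):
    """Model fitting failed irrecoverably (non-finite likelihood, size budget)."""
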