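"""Exception hierarchy for civmtrace.

All package errors derive from :class:`CivmError` so callers can catch one
base class at pipeline boundaries.
"""


class CivmError(Exception):
    """Base class for all civmtrace errors."""


class AcqusParseError(CivmError):
    """A required key is missing or malformed in Bruker acqus parameter text."""


class AxisMismatchError(CivmError):
    """Spectra being assembled do not share a common ppm axis."""


class DuplicateTimeError(CivmError):
    """Two acquisition records carry the same start clock."""


class EmptyResultError(CivmError):
    """A trim/truncate operation would leave no data."""


class InsufficientDataError(CivmError):
    """Too few timepoints for the requested operation (e.g. block summation)."""


class ReferenceNotFoundError(CivmError):
    """No detectable reference (DSS) peak in the search window.

    Carries ``timepoint`` — the index of the offending spectrum.
    """

    def __init__(self, message: str, timepoint: int | None = None):
        super().__init__(message)
        self.timepoint = timepoint


class ScalingError(CivmError):
    """Ridge compositing cannot compute a scale factor (empty support or
    nonpositive support mean)."""


class CalibrationError(CivmError):
    """Titration fit is unusable (too few points or non-monotone over range)."""


class OutOfRangeError(CivmError):
    """A ppm value lies outside the calibrated titration span.

    Carries ``timepoint`` when raised for one element of a trajectory.
    """

    def __init__(self, message: str, timepoint: int | None = None):
        super().__init__(message)
        self.timepoint = timepoint


class SpecValidationError(CivmError):
    """A synthetic series / run configuration failed validation.

    ``fields`` lists the offending field names.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []
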