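"""Exception hierarchy shared across the pipeline stages."""


class HydrofdaError(Exception):
    """Base class for all package errors."""


class FormatError(HydrofdaError):
    """Input file is malformed (missing columns, unparseable layout)."""


class EmptyInputError(HydrofdaError):
    """Input file contains no data rows."""


class ParameterError(HydrofdaError):
    """A configuration or function parameter is out of its valid range."""


class InsufficientDataError(HydrofdaError):
    """Too few observations to carry out the requested computation."""


class MissingSeasonError(InsufficientDataError):
    """No qualifying measurements for a season; it must be excluded."""


class AlignmentError(HydrofdaError):
    """Objects that must share a grid or index set do not."""


class DegenerateResponseError(HydrofdaError):
    """Response vector has zero variance; R-squared is undefined."""
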