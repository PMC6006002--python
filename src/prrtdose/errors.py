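"""Exception hierarchy shared across the package."""


class PrrtDoseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PrrtDoseError, ValueError):
    """An input value is outside its physical/mathematical domain."""


class InsufficientDataError(PrrtDoseError, ValueError):
    """Too few measurements to perform the requested operation."""


class NonPhysicalFitError(PrrtDoseError, ValueError):
    """A time-activity fit produced a non-decaying (lambda <= 0) curve."""


class ConfigurationError(PrrtDoseError, ValueError):
    """A dose-factor table or run configuration is incomplete/inconsistent."""


class InputError(PrrtDoseError, ValueError):
    """Structurally invalid user input (missing organ, length mismatch...)."""


class ParseError(PrrtDoseError, ValueError):
    """A data file failed validation; message names file/row/column."""
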