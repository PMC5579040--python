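"""Exception hierarchy shared across the package."""


class ClsenseError(Exception):
    """Base class for all package errors."""


class SchemaError(ClsenseError):
    """A table is missing required columns or has malformed values."""


class ValidationError(ClsenseError):
    """Data violates an invariant; the message names the offending record."""


class FitError(ClsenseError):
    """A numerical fit failed to converge; carries diagnostics in the message."""


class IdentifiabilityError(FitError):
    """The requested fit is not identifiable from the data provided."""


class AnalysisError(ClsenseError):
    """An analysis step received inputs it cannot operate on."""


class NoCrossingError(AnalysisError):
    """A difference I-V relation never crosses zero within the command range."""


class MultipleCrossingsError(AnalysisError):
    """A difference I-V relation crosses zero more than once."""
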