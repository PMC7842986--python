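"""Exception hierarchy."""


class FgmsimError(Exception):
    """Base class for all package errors."""


class ValidationError(FgmsimError, ValueError):
    """An input violated a documented invariant; the message names the field."""


class BoundaryError(FgmsimError, LookupError):
    """A required surface cell (age, year) is not available."""


class SeparationError(FgmsimError):
    """Logistic fit failed due to (quasi-)complete separation.

    Re-fit with ``regularized=True`` or collapse sparse covariate levels.
    """
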