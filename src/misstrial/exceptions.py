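"""Exception types used across the package."""


class MisstrialError(Exception):
    """Base class for all package errors."""


class DataValidationError(MisstrialError):
    """A record or input table violates a structural invariant."""


class DegenerateDataError(MisstrialError):
    """The data cannot identify the requested model (e.g. no nonresponders,
    a single outcome class among responders, or perfect separation)."""


class FixtureError(MisstrialError, KeyError):
    """Unknown packaged fixture name."""
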