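"""Exception types shared across the package."""

from __future__ import annotations


class RadfracError(Exception):
    """Base class for all radfrac errors."""


class InvalidParameterError(RadfracError, ValueError):
    """A model parameter, dose or configuration value is out of range."""


class DegeneracyError(RadfracError, ArithmeticError):
    """The simulated state was driven non-positive.

    Carries the day index on which the degeneracy occurred.
    """

    def __init__(self, message: str, day: int):
        super().__init__(message)
        self.day = day


class UndefinedCorrelationError(RadfracError, ValueError):
    """Pearson correlation requested for a constant or too-short series."""
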