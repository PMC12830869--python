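"""Exception taxonomy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError (and
subclasses) -> 3, NumericalError (and subclasses) -> 4.
"""

from __future__ import annotations


class OxCircuitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OxCircuitError):
    """Malformed or incomplete configuration; message names the key path."""


class DataError(OxCircuitError):
    """Invalid input data (shape, ordering, preconditions)."""


class CircuitDomainError(DataError, ValueError):
    """A physical parameter is outside its admissible domain."""


class InconsistentTraceError(DataError):
    """Extracted quantities violate the model's ordering (e.g. Pr <= Pw)."""


class DegenerateSegmentError(DataError):
    """A trace segment carries no usable signal (flat within tolerance)."""


class NumericalError(OxCircuitError):
    """Numerical failure: instability, non-convergence."""


class FitError(NumericalError):
    """Nonlinear fit failed; carries the last iterate when available."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class IntegrationError(NumericalError):
    """Fixed-step integration left the physical range; reduce the step."""
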