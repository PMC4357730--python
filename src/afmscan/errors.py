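"""Exception hierarchy used across the pipeline.

Exit-code mapping for the CLI lives in :mod:`afmscan.cli`; library code
raises these and never calls ``sys.exit``.
"""


class AfmscanError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AfmscanError, ValueError):
    """A configuration or function parameter violates its contract."""


class InvalidInputError(AfmscanError, ValueError):
    """Input data (tables, spectra, images) violates a precondition."""


class InvalidTraceError(AfmscanError, ValueError):
    """A backbone polyline is unusable (too few points, out-of-range arc)."""


class UnmeasurableComplexError(AfmscanError):
    """A complex cannot be measured (insufficient arm length, clipped mask).

    Callers iterating over many complexes catch this and flag the record
    excluded rather than aborting the run.
    """


class FitFailureError(AfmscanError):
    """A least-squares fit did not converge; carries residuals when known."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class PlacementError(AfmscanError):
    """A fragment could not be placed on the raster within the retry budget."""

    def __init__(self, message, fragment_index=None):
        super().__init__(message)
        self.fragment_index = fragment_index
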