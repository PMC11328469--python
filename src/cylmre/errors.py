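"""Exception hierarchy for cylmre.

All errors derive from :class:`CylmreError` so callers can catch the package's
failures with one clause; most also derive from :class:`ValueError` because
they signal invalid inputs rather than internal faults.
"""


class CylmreError(Exception):
    """Base class for all cylmre errors."""


class InvalidInputError(CylmreError, ValueError):
    """An argument violates a documented precondition."""


class SingularMediumError(InvalidInputError):
    """Zero complex modulus: the wave equation has no finite wavenumber."""


class UndersampledError(InvalidInputError):
    """Fewer time offsets than needed to isolate the drive harmonic."""


class EmptyProfileError(InvalidInputError):
    """No pixels fall inside the tube when extracting a radial profile."""


class InsufficientDataError(InvalidInputError):
    """Too few valid frequencies for a rheological fit."""


class EmptyCohortError(InvalidInputError):
    """A cohort configuration with no samples in any grade."""


class PlacementError(CylmreError, RuntimeError):
    """Nucleus placement failed: packing density infeasible within retries."""


class InvalidGradeError(InvalidInputError):
    """Tumour regression grade outside the 1-5 scale."""


class PipelineStageError(CylmreError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
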