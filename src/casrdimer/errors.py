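"""Exception hierarchy for the casrdimer pipeline.

Every stage raises a subclass of :class:`CasrDimerError` so callers (and the
CLI) can attribute a failure to a pipeline stage without string matching.
"""


class CasrDimerError(Exception):
    """Base class for all casrdimer errors."""


class DomainError(CasrDimerError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InsufficientDataError(CasrDimerError):
    """Too few distinct concentrations (or points) to attempt a fit."""


class DegenerateFitError(CasrDimerError):
    """The data carry no usable concentration dependence (flat responses)."""


class ConvergenceError(CasrDimerError):
    """The optimizer failed to converge even after multi-start restarts."""


class AlignmentError(CasrDimerError):
    """Concentration grids of two tables do not match; no silent interpolation."""


class NormalizationError(CasrDimerError):
    """A fluorescence trace violates the F0 baseline-normalization contract."""


class ConfigError(CasrDimerError):
    """A pipeline configuration failed schema validation.

    ``field`` holds a dotted path to the offending entry.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")
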