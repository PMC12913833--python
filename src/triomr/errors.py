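"""Typed error hierarchy.

Every failure mode the pipeline can hit has a distinct class so callers
(and the CLI) can branch on condition rather than message text.
"""


class TriomrError(Exception):
    """Base class for all package errors."""


class SchemaError(TriomrError):
    """A required column is missing from an input table."""


class SumStatsValidationError(TriomrError):
    """A row violates the per-variant invariants; message names the row."""


class DuplicateVariantError(TriomrError):
    """Duplicate variant identifiers within one trait."""


class LDMatrixError(TriomrError):
    """LD matrix shape, range, or symmetry violation."""


class MissingEAFError(TriomrError):
    """An operation needing effect-allele frequency met a missing value."""


class NoInstrumentsError(TriomrError):
    """A filter left zero instruments; callers decide whether fatal."""


class InsufficientInstrumentsError(TriomrError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(TriomrError):
    """Single-instrument estimate with a zero exposure effect."""


class LDCoverageError(TriomrError):
    """A clumping candidate is absent from the LD matrix."""


class RankDeficiencyError(TriomrError):
    """Regression design is rank deficient (all exposure effects equal)."""


class AlignmentError(TriomrError):
    """Two traits' variant lists do not match where identity is required."""


class PipelineStageError(TriomrError):
    """A pipeline stage failed; message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
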