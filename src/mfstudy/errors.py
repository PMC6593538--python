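"""Typed exceptions raised across the pipeline.

Every malformed input raises one of these; nothing is silently dropped.
"""


class MFStudyError(Exception):
    """Base class for all package errors."""


class FormatError(MFStudyError):
    """A tabular input is structurally malformed (e.g. a missing column)."""


class ValidationError(MFStudyError):
    """A record violates a domain invariant (e.g. a mark outside its ROI)."""


class PoolingAmbiguityError(MFStudyError):
    """Two marks from the same (reader, modality) fell into one candidate cluster."""


class IncompleteTruthError(MFStudyError):
    """A pooled candidate has no label from either the consensus rule or the panel."""


class TruthConflictError(MFStudyError):
    """The adjudication panel contradicts an auto-consensus true candidate."""


class DegenerateTruthError(MFStudyError):
    """The truth set has no true (or no false) candidates; Se/Sp are undefined."""


class DegenerateJackknifeError(MFStudyError):
    """Deleting one slide leaves no true or no false candidates."""


class InsufficientDataError(MFStudyError):
    """Too few observations for the requested estimator."""


class UnstableVarianceError(MFStudyError):
    """A variance estimate is non-positive and cannot support inference."""


class ConfigError(MFStudyError):
    """A configuration value is invalid or infeasible (e.g. an over-crowded ROI)."""
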