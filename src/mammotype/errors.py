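"""Exception hierarchy for mammotype.

Every error raised on bad user input derives from :class:`MammotypeError`
so callers can catch one base class at pipeline boundaries.
"""


class MammotypeError(Exception):
    """Base class for all mammotype errors."""


class InvalidConfigError(MammotypeError):
    """Synthetic-cohort configuration violates an invariant."""


class PreprocessingError(MammotypeError):
    """Expression preprocessing failed (missing values, unmapped probes, ...)."""


class EmptyResultError(MammotypeError):
    """An operation filtered away every row/record."""


class InsufficientOverlapError(MammotypeError):
    """Gene overlap between a matrix and a reference set is below the floor."""


class ClusteringError(MammotypeError):
    """Hierarchical clustering or cluster-significance preconditions violated."""


class InvalidLabelsError(MammotypeError):
    """Group/cluster labels are malformed (empty group, wrong count, ...)."""


class SignatureError(MammotypeError):
    """A gene signature is empty, degenerate, or refers to absent genes."""


class MissingGeneError(MammotypeError):
    """A named gene is absent from the expression matrix."""


class MalformedRecordError(MammotypeError):
    """A variant record violates the record invariants."""


class InvalidReferenceError(MammotypeError):
    """A reference signature matrix fails validation."""


class EmptyCatalogError(MammotypeError):
    """A 96-context catalog has zero total count."""


class IncomparableProfilesError(MammotypeError):
    """CNA profiles share no gene universe."""


class InvalidTableError(MammotypeError):
    """A contingency table is empty or malformed."""


class InvalidInputError(MammotypeError):
    """Generic invalid statistical input (empty sample, ...)."""
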