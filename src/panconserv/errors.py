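"""Exception hierarchy.

Validation/contract problems (bad inputs, malformed files, impossible
configurations) raise :class:`ValidationError` subclasses; numerical or
computational failures raise :class:`ComputationError`. The CLI maps the
former to exit code 2 and the latter to exit code 3.
"""


class PanconservError(Exception):
    """Base class for all package errors."""


class ValidationError(PanconservError):
    """Input violates a documented contract or invariant."""


class ParseError(ValidationError):
    """A file could not be parsed into the expected structure."""


class MissingMetadataError(ValidationError):
    """A sample present in the counts has no metadata record."""


class RecipeError(ValidationError):
    """An in-silico pooling recipe is inconsistent."""


class ContractError(ValidationError):
    """An operation was called with arguments outside its precondition."""


class ComputationError(PanconservError):
    """A numerical stage failed on otherwise valid input."""


class DegenerateSampleError(ComputationError):
    """A sample admits no size factor (zero median of ratios)."""


class InsufficientReplicationError(ComputationError):
    """No group has the replication needed for dispersion estimation."""
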