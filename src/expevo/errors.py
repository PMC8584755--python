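"""Typed errors and warnings.

Every validation failure in the package raises one of these; nothing is
silently coerced.
"""


class ExpevoError(Exception):
    """Base class for all package errors."""


class ValidationError(ExpevoError, ValueError):
    """Invalid input data or parameters."""


class DuplicateLabelError(ValidationError):
    """A gene, species or animal label occurs more than once."""


class NonNumericValueError(ValidationError):
    """A cell that must be numeric is not (names the row/column)."""


class RaggedTableError(ValidationError):
    """A tabular file is not rectangular."""


class SchemaError(ValidationError):
    """A CSV header or column content does not match the expected schema."""


class MonotonicityError(ValidationError):
    """Time points within a kinetics series are not strictly increasing."""


class NewickError(ValidationError):
    """Malformed Newick input or missing branch lengths."""


class ConstantVectorError(ValidationError):
    """Spearman correlation undefined: one of the vectors is constant."""


class DegenerateFitWarning(UserWarning):
    """A maximum-likelihood variance hit its lower floor."""


class UnrootedTreeWarning(UserWarning):
    """An unrooted tree was midpoint-rooted before a Brownian-motion fit."""


class NegativeEdgeWarning(UserWarning):
    """Neighbor joining estimated a negative edge length (clamped to 0)."""
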