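"""Exception hierarchy for the toolkit."""

from __future__ import annotations


class SemannotError(Exception):
    """Base class for all toolkit errors."""


class DomainSyntaxError(SemannotError):
    """The domain file does not conform to the dialect grammar."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class DomainSemanticError(SemannotError):
    """The domain file parses but violates a structural invariant.

    The message names the offending declaration (unknown type, arity
    mismatch, unassigned entity-valued fluent, ...).
    """


class UnresolvableLabelError(SemannotError):
    """One or more annotation labels are not in the domain's label set L.

    ``entries`` lists ``(index, label)`` pairs so the annotation can be
    repaired in one pass.
    """

    def __init__(self, entries: list[tuple[int, str]]):
        self.entries = list(entries)
        listing = "; ".join(f"step {i}: {lab!r}" for i, lab in self.entries)
        super().__init__(f"labels not in the domain label set: {listing}")


class PreconditionError(SemannotError):
    """An action was applied in a state where its precondition fails."""

    def __init__(self, label: str, failed_condition: str):
        self.label = label
        self.failed_condition = failed_condition
        super().__init__(f"precondition of {label!r} violated: {failed_condition}")


class EvaluationError(SemannotError):
    """An expression could not be evaluated (unknown term, non-numeric operand)."""


class AnnotationFormatError(SemannotError):
    """An annotation file is malformed (bad time stamp, end <= start, duplicates)."""


class MetricsUndefinedError(SemannotError):
    """Reliability metrics requested on empty input (both tiers empty)."""
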