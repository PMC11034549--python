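"""Exception hierarchy.

Every stage of the synthesis pipeline raises a subclass of
:class:`GcpsynthError` so callers (and the CLI) can tag failures by stage.
"""


class GcpsynthError(Exception):
    """Base class for all package errors."""


class InvalidModelError(GcpsynthError):
    """A Kruskal model's factors/weights are mutually inconsistent."""


class DomainError(GcpsynthError):
    """A (data, model) value pair lies outside the loss function's domain."""


class DegenerateVariableError(GcpsynthError):
    """A variable is constant (or empty) where variation is required."""


class UndefinedScoreError(GcpsynthError):
    """Fit score is undefined (all observed entries are zero)."""


class DuplicateCellError(GcpsynthError):
    """The same (patient, variable, visit) cell appears more than once."""


class FormatError(GcpsynthError):
    """Malformed long-format CSV or model artifact."""
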