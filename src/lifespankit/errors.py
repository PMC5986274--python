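"""Exception hierarchy shared across the package.

The CLI maps :class:`ValidationError` (bad inputs) to exit code 2 and
:class:`NotComputableError` (a statistic that is undefined for the given
data, e.g. a Kaplan-Meier median when the curve never reaches 0.5) to
exit code 3.
"""


class ValidationError(ValueError):
    """Input violates a data-model invariant (duplicate ids, bad labels...)."""


class FormatError(ValidationError):
    """A table does not conform to the expected on-disk format."""


class NotComputableError(RuntimeError):
    """The requested statistic is undefined for the given data."""


class UndefinedMedianError(NotComputableError):
    """Survival curve never reaches 0.5, so the median does not exist."""
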