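"""Exception types shared across the package.

Input/validation problems raise :class:`DataValidationError` (a ValueError),
numeric degeneracies that make a statistic undefined raise
:class:`DegenerateStatisticError` (an ArithmeticError).  The CLI maps the two
families to distinct exit codes.
"""


class DataValidationError(ValueError):
    """An input file or in-memory object violates a documented precondition."""


class DegenerateStatisticError(ArithmeticError):
    """A statistic is undefined for this input (e.g. zero spread everywhere)."""
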