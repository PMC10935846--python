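"""Exception types shared across the pipeline stages."""


class TradeoffError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(TradeoffError):
    """A stage was called on data violating its preconditions.

    Raised e.g. when singular-value reconstruction or correlation is
    requested on a matrix that still contains missing values, or when a
    zero-variance condition is passed to standardisation.
    """


class EmptyResultError(TradeoffError):
    """An operation removed or excluded every row/column/member."""
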