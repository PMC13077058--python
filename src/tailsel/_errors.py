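"""Package exception hierarchy."""


class TailselError(Exception):
    """Base class for tailsel errors."""


class InvalidInputError(TailselError, ValueError):
    """Input data violates a contract (non-finite, wrong shape, bad label)."""


class UndefinedStatisticError(TailselError, ValueError):
    """A statistic is undefined for the given input (e.g. constant vectors)."""


class DomainError(TailselError, ValueError):
    """A parameter lies outside the mathematical domain of a transform."""
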