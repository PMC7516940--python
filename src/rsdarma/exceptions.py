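"""Exception hierarchy."""


class RsdarmaError(Exception):
    """Base class for all package errors."""


class InvalidModelError(RsdarmaError, ValueError):
    """Model specification violates a structural constraint."""


class DegenerateDistributionError(RsdarmaError, ValueError):
    """A dependence measure's denominator vanishes (one-point marginal)."""


class NominalRangeError(RsdarmaError, TypeError):
    """An ordinal-only quantity was requested for a nominal range."""


class ReducibleChainError(RsdarmaError, ValueError):
    """Transition matrix is not irreducible; stationary distribution not unique."""


class PartitionBlowupError(RsdarmaError, ValueError):
    """Partition enumeration would exceed the configured cap."""


class UnknownSymbolError(RsdarmaError, ValueError):
    """A series contains a symbol outside the declared state set."""


class ZeroLikelihoodError(RsdarmaError, ValueError):
    """An observed transition has model probability zero."""

    def __init__(self, t: int, prev, cur):
        self.t = t
        self.prev = prev
        self.cur = cur
        super().__init__(
            f"observed transition {prev!r} -> {cur!r} at position {t} "
            f"has probability 0 under the model"
        )
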