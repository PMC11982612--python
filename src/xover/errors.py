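"""Exception hierarchy for the xover pipeline."""


class XoverError(Exception):
    """Base class for all xover errors."""


class ValidationError(XoverError):
    """Input object violates a structural invariant."""


class ParseError(XoverError):
    """A table on disk could not be parsed."""


class SchemaError(XoverError):
    """Two objects that must align (matrix vs. map) do not."""


class InvalidModelError(XoverError):
    """A simulation model parameter is out of its domain."""


class DegenerateDesignError(XoverError):
    """A regression design matrix is rank-deficient (constant predictor)."""


class EmptyPopulationError(XoverError):
    """A filtering step removed every individual."""


class InfiniteKLError(XoverError):
    """KL(P, Q) is infinite: P occupies a bin where Q is empty.

    The offending bin indices are carried in ``bins``.
    """

    def __init__(self, bins):
        self.bins = list(bins)
        super().__init__(
            f"infinite KL divergence: P occupies empty-Q bins {self.bins}; "
            "rebuild the distributions with a pseudocount to proceed"
        )
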