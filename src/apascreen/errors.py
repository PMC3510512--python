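"""Exception types shared across the package."""


class APAScreenError(Exception):
    """Base class for all package errors."""


class ParseError(APAScreenError):
    """A text input could not be parsed; message names the file and line."""


class ValidationError(APAScreenError):
    """An input violated a documented invariant."""


class NoProductError(APAScreenError):
    """In-silico PCR found no productive primer placement."""


class AmbiguousProductError(APAScreenError):
    """In-silico PCR found multiple productive placements.

    Attributes
    ----------
    lengths : list of int
        Amplicon lengths of every productive placement, ascending.
    """

    def __init__(self, lengths):
        self.lengths = sorted(lengths)
        super().__init__(
            "ambiguous product: %d placements with lengths %s"
            % (len(self.lengths), self.lengths)
        )
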