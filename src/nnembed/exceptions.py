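"""Exception hierarchy shared across the package."""


class NNEmbedError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NNEmbedError):
    """A network or annotation file could not be parsed."""


class DimensionError(NNEmbedError):
    """Array shapes are inconsistent with what the operation requires."""


class ConfigurationError(NNEmbedError):
    """Parameters are out of range or mutually inconsistent."""


class EmptyNetworkError(NNEmbedError):
    """An operation produced or received a network with no nodes."""


class InfeasibleSwapError(NNEmbedError):
    """Edge relocation cannot be completed under the requested constraints."""


class TrainingDivergenceError(NNEmbedError):
    """The loss became non-finite during optimisation.

    Carries the training history recorded up to the failing epoch.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history


class UndefinedValueError(NNEmbedError):
    """A quantity is undefined for the given input (e.g. recall on an edgeless network)."""


class StatisticsError(NNEmbedError):
    """A statistical routine received groups too small to be tested."""


class AlignmentError(NNEmbedError):
    """Two reports or curves do not refer to the same networks/fractions."""
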