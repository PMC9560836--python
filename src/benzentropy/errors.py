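"""Exception hierarchy shared across the package.

``BenzentropyError`` is the catch-all the CLI maps to exit status 1;
``ParameterError`` subclasses ``ValueError`` so plain library users get the
idiomatic exception type for bad arguments.
"""


class BenzentropyError(Exception):
    """Base class for all errors raised by this package."""


class UnknownVertexError(BenzentropyError, KeyError):
    """A vertex identifier is not present in the graph."""


class ParameterError(BenzentropyError, ValueError):
    """A parameter is outside its admissible range or of the wrong kind."""


class RegimeError(ParameterError):
    """Parameters are outside the validity regime of a printed table."""


class BasisMismatchError(ParameterError):
    """An edge partition's basis does not match the weight scheme's basis."""


class DomainError(BenzentropyError, ValueError):
    """An input is outside the mathematical domain of an operation
    (e.g. an ABC weight at label pair (1, 1), or an empty edge set)."""


class GenerationError(BenzentropyError):
    """A generated graph failed its structural validation contract."""
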