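"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems -> 2,
data/format problems -> 3, contract violations -> 4.
"""


class ImageChainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImageChainError):
    """Invalid chain/protocol configuration (unknown algorithm, bad key...)."""


class ArgumentError(ImageChainError):
    """A call violated an operation precondition (out-of-range value...)."""


class FormatError(ImageChainError):
    """A file could not be parsed in its declared format."""


class DataError(ImageChainError):
    """Input data is structurally valid but unusable (missing images...)."""


class ContractError(ImageChainError):
    """Two fitted/configured components disagree (column provenance,
    patch geometry, plugin output-length constancy...)."""


class DegenerateInputError(ArgumentError):
    """An input with no usable signal (e.g. zero total intensity)."""


class GenerationError(ImageChainError):
    """A synthetic-data spec is infeasible (e.g. blob separation)."""
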