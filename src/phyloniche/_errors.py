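"""Exception hierarchy shared across the package."""


class PhylonicheError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhylonicheError):
    """Input violates a structural invariant (ragged alignment, bad header, ...)."""


class AlphabetError(ValidationError):
    """Sequence contains a character outside {A, C, G, T, N, -}."""


class DegenerateInputError(PhylonicheError):
    """Input is structurally valid but leaves nothing to compute on."""


class InsufficientSampleError(PhylonicheError):
    """Too few samples/sequences for the requested statistic."""
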