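"""Exception hierarchy shared across the package."""


class HEGenomeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HEGenomeError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(HEGenomeError, ValueError):
    """Operands are malformed or mutually inconsistent (e.g. modulus mismatch)."""


class NoBatchingError(HEGenomeError):
    """The requested (m, t) pair admits no CRT slot structure."""


class CapacityError(HEGenomeError):
    """More data than the ring/slot layout can hold."""


class ParameterSearchError(HEGenomeError):
    """No admissible parameter set found within the search cap."""


class KeyGenError(HEGenomeError):
    """Key generation failed (e.g. repeated non-invertible f)."""


class DepthBudgetError(HEGenomeError):
    """A homomorphic operation would exceed the configured multiplicative depth."""


class DecryptionFailure(HEGenomeError):
    """Measured ciphertext noise is too close to the wrap-around bound."""


class EncodingError(HEGenomeError, ValueError):
    """Genomic data cannot be encoded (unknown genotype, over-long ALT, ...)."""


class PipelineError(HEGenomeError):
    """A pipeline-level validation failed (t-bound, params mismatch, ...)."""


class UndefinedStatisticError(HEGenomeError):
    """The chi-square statistic is undefined (monomorphic site / zero margin)."""
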