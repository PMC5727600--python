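"""Exception types shared across the package."""


class InvalidDesignError(ValueError):
    """A sampling design violates its geometric invariants."""


class ValidationError(ValueError):
    """Malformed or out-of-range input data."""


class AlignmentMissingError(ValueError):
    """A section pair was used for counting without an alignment transform."""


class NoSignalError(ValueError):
    """An image is empty or constant and cannot be aligned."""


class PackingError(RuntimeError):
    """Particle placement could not satisfy the separation constraint."""


class EmptySeriesError(ValueError):
    """A count series required to be non-empty was empty."""


class UndefinedStatisticError(ValueError):
    """A statistic (CE, CV, rho) is undefined for the given input."""
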