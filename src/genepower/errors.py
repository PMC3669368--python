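"""Exception hierarchy for the genepower package."""


class GenePowerError(Exception):
    """Base class for package-specific errors."""


class ParameterError(GenePowerError, ValueError):
    """An argument is outside its documented domain."""


class FeasibilityError(GenePowerError, ValueError):
    """A requested correlation violates the binary Frechet bounds, or a
    disease-model parameter combination implies a probability above 1."""


class SamplingError(GenePowerError, ValueError):
    """A case-control sample cannot be drawn (e.g. too few cases in the
    simulated population)."""


class NumericalError(GenePowerError, RuntimeError):
    """A numerical routine failed beyond its fallbacks (e.g. Cholesky of the
    LD matrix even after diagonal jitter)."""
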