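"""Exception hierarchy.

All user-facing failures derive from :class:`RiboneutralError` so callers can
catch one type at the CLI boundary.
"""


class RiboneutralError(Exception):
    """Base class for all package errors."""


class InputError(RiboneutralError):
    """Invalid argument values or inconsistent inputs."""


class FormatError(RiboneutralError):
    """A file or text payload does not parse in the declared dialect."""


class GenerationError(RiboneutralError):
    """A sequence generator could not satisfy its constraints."""


class TrainingError(RiboneutralError):
    """Model fitting diverged or produced non-finite parameters."""


class SamplingError(RiboneutralError):
    """An MCMC sampler encountered a non-finite score or invalid state."""


class NumericalError(RiboneutralError):
    """A numerical routine hit a degenerate problem (e.g. rank-0 PCA basis)."""


class FitError(RiboneutralError):
    """A statistical fit had too few or degenerate data."""
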