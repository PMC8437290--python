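"""Exception hierarchy.

All numerical-domain failures derive from :class:`StochlifeError` so callers
(and the CLI) can distinguish usage errors from model-domain errors.
"""


class StochlifeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StochlifeError, ValueError):
    """A parameter bundle violates a model invariant; names the offending field."""


class DegenerateInputError(StochlifeError, ValueError):
    """An operation whose formula divides by a vanishing quantity (e.g. sigma1=0)."""


class DivergenceError(StochlifeError, ArithmeticError):
    """An integral or series that does not converge for the given inputs."""


class ConfigurationError(StochlifeError, ValueError):
    """A simulation or grid configuration that cannot represent the problem."""
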