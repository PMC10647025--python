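"""Exception hierarchy for the ribecho pipeline.

Every error raised by the package derives from :class:`RibEchoError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors. Subclasses mirror the pipeline stages: configuration validation,
simulation, file parsing, alignment, model fitting, data/contract checks.
"""


class RibEchoError(Exception):
    """Base class for all errors raised by ribecho."""


class ConfigurationError(RibEchoError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class SimulationError(RibEchoError):
    """The requested trace cannot be synthesized (e.g. echo beyond trace end)."""


class ParseError(RibEchoError):
    """A trace or manifest file could not be parsed."""


class FormatError(RibEchoError):
    """A file parsed but violates the expected format contract."""


class AlignmentError(RibEchoError):
    """Stimulus onset could not be detected; the trace is unusable."""


class FittingError(RibEchoError):
    """A model fit is infeasible or failed to converge."""


class DataError(RibEchoError, ValueError):
    """Input data violates a precondition (missing field, empty class, ...)."""


class ContractError(RibEchoError):
    """Two artifacts that must agree (e.g. feature schema hashes) do not."""
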