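"""Exception hierarchy.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2,
:class:`DataError` -> 3, :class:`NoEventsError` -> 4.
"""


class RunTumbleError(Exception):
    """Base class for all package errors."""


class ConfigError(RunTumbleError, ValueError):
    """Invalid configuration or parameter bundle."""


class DataError(RunTumbleError, ValueError):
    """Malformed or insufficient input data."""


class NoEventsError(DataError):
    """A trajectory contained no supra-threshold runs; nothing to estimate."""


class DomainError(RunTumbleError, ValueError):
    """A model law was evaluated outside its domain of validity."""


class StabilityError(RunTumbleError, ValueError):
    """An explicit time step violates the scheme's stability bound."""
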