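"""Typed failures raised across the pipeline stages.

Every stage raises a subclass of :class:`MeaGdnError` so callers (and the CLI)
can distinguish configuration problems, data problems and numerical failures.
"""


class MeaGdnError(Exception):
    """Base class for all package errors."""


class ConfigError(MeaGdnError):
    """Invalid or inconsistent configuration."""


class DataError(MeaGdnError):
    """Input data violates a stage precondition."""


class NoDetectableActivityError(DataError):
    """No spike could be detected even after relaxing the threshold factor."""


class NumericalError(MeaGdnError):
    """A numerical routine failed (non-finite values, non-convergence)."""
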