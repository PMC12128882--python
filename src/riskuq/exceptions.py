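"""Exception hierarchy.

All package errors derive from :class:`RiskUQError` so callers (and the CLI)
can distinguish data/model problems from programming errors.
"""


class RiskUQError(Exception):
    """Base class for all riskuq errors."""


class InputError(RiskUQError, ValueError):
    """Malformed or inconsistent user input (shapes, values, columns)."""


class DegenerateOutcomeError(RiskUQError, ValueError):
    """Outcome vector contains a single class; a risk model cannot be fitted."""


class ConvergenceError(RiskUQError, RuntimeError):
    """Model fitting failed to converge (e.g. perfect separation)."""


class ExtrapolationError(RiskUQError, ValueError):
    """Query outside the observed range of estimated risks."""


class SerializationError(RiskUQError, ValueError):
    """Unreadable, truncated, or version-incompatible artefact file."""
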