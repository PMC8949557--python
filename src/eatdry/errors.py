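"""Exception hierarchy for eatdry.

All library errors derive from :class:`EatdryError` so callers can catch one
base class at the CLI boundary.
"""


class EatdryError(Exception):
    """Base class for all eatdry errors."""


class DomainError(EatdryError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InvalidStateError(EatdryError, ValueError):
    """A moisture/thermodynamic state violates its invariants (e.g. M0 <= Me)."""


class UnreachableMoistureError(EatdryError, ValueError):
    """The requested target moisture is outside the reachable band of the
    drying curve (moisture ratio not in (a, a+b))."""


class CannotActuateError(EatdryError, RuntimeError):
    """The discharge interval cannot realize the requested accumulated
    temperature (grain is at or below its equilibrium temperature)."""


class ConfigError(EatdryError, ValueError):
    """A configuration file or scenario specification is invalid."""
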