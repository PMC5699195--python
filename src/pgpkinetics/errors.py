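"""Exception hierarchy shared across the package."""


class PgpKineticsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PgpKineticsError, ValueError):
    """A scalar or array argument violates an operation's precondition."""


class InvalidStateError(PgpKineticsError, ValueError):
    """A system state violates its invariants (e.g. negative concentration)."""


class ConfigurationError(PgpKineticsError, ValueError):
    """A configuration references unknown drugs, keys, or inconsistent options."""


class MisuseError(PgpKineticsError, RuntimeError):
    """An operation was called outside the regime where it is defined."""


class IntegrationError(PgpKineticsError, RuntimeError):
    """The ODE integrator or steady-state solver failed.

    Carries the sweep value being processed when raised from a sweep, so the
    failing condition can be reported to the user.
    """

    def __init__(self, message: str, sweep_value: float | None = None):
        super().__init__(message)
        self.sweep_value = sweep_value
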