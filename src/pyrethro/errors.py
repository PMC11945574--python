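"""Exception hierarchy shared across the package."""


class PyrethroError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(PyrethroError, KeyError):
    """An id referenced by a matrix or query is not declared in the registry."""


class ValidationError(PyrethroError, ValueError):
    """A declared object violates one of its invariants (mass balance, sign, range)."""


class DomainError(PyrethroError, ValueError):
    """An operation was called on inputs outside its mathematical domain."""


class ConfigurationError(PyrethroError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class IntegrationError(PyrethroError, RuntimeError):
    """The ODE solver produced a non-finite state."""


class ConvergenceError(PyrethroError, RuntimeError):
    """An MCMC stage failed its convergence diagnostic."""
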