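"""Exception hierarchy shared by all modules."""


class AbilityGameError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AbilityGameError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SolverError(AbilityGameError, RuntimeError):
    """A numerical solver failed to converge; carries diagnostics in args."""


class ConfigError(AbilityGameError, ValueError):
    """A configuration value or file is invalid; names the offending key."""


class ClassificationError(AbilityGameError, ValueError):
    """classify_singular was called on a point that is not singular."""
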