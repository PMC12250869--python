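"""Exception hierarchy shared across the package."""


class MixprocError(Exception):
    """Base class for all package-specific failures."""


class ArgumentError(MixprocError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(ArgumentError):
    """A factor value lies outside its variation domain."""


class FixtureError(MixprocError):
    """The packaged dataset failed its integrity check."""


class DataError(MixprocError):
    """Input data are unusable (missing responses, bad columns, ...)."""


class FittingError(MixprocError):
    """Least-squares fitting cannot proceed (rank deficiency, too few runs)."""


class DegenerateResponseError(FittingError):
    """The response is constant; ANOVA quantities are undefined."""


class ConfigError(MixprocError):
    """A run configuration violates the schema."""
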