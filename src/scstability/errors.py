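"""Exception types shared across the package."""


class ScStabilityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScStabilityError, ValueError):
    """A configuration object violates its invariants; message names the field."""


class FormatError(ScStabilityError, ValueError):
    """An on-disk input does not match its declared format."""


class InputError(ScStabilityError, ValueError):
    """Valid-format input that violates an operation's precondition."""


class DegenerateTestError(ScStabilityError, ValueError):
    """A statistical test cannot be computed (e.g. zero-variance paired differences)."""


class DependencyError(ScStabilityError, RuntimeError):
    """A pipeline stage was requested but a stage it depends on is disabled."""
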