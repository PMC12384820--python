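"""Exception hierarchy for mechanoecg."""


class MechanoEcgError(Exception):
    """Base class for all package errors."""


class InputError(MechanoEcgError):
    """Unreadable, malformed, or inconsistent input data."""


class ConfigError(MechanoEcgError):
    """Invalid configuration value."""


class StandardizationError(MechanoEcgError):
    """A segment with zero variance cannot be standardized."""


class EvaluationError(MechanoEcgError):
    """An evaluation quantity is undefined for the given inputs."""
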