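"""Exception types shared across the package."""


class LakeHealthError(Exception):
    """Base class for package errors."""


class ConfigurationError(LakeHealthError):
    """A run configuration, parameter table, or policy is invalid."""


class ValidationError(LakeHealthError):
    """Input data violate a precondition (negative biomass, bad shapes...)."""


class UndefinedIndicatorError(LakeHealthError):
    """An indicator is mathematically undefined for the given input,
    e.g. specific eco-exergy of a zero-biomass community."""
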