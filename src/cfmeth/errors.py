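"""Exception types shared across the package."""


class CfMethError(Exception):
    """Base class for package errors."""


class ConfigError(CfMethError, ValueError):
    """A configuration object is internally inconsistent or out of range."""


class InsufficientReplicatesError(CfMethError, ValueError):
    """A group-comparison operation received fewer than 2 samples in a group."""


class EmptyInputError(CfMethError, ValueError):
    """An operation that requires at least one record received none."""
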