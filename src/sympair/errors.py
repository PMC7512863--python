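"""Exception hierarchy shared by all sympair modules."""


class SympairError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SympairError):
    """An invalid or unknown configuration value (the offending key is named)."""


class DomainError(SympairError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class StructuralError(SympairError):
    """A violated structural precondition (mismatched dimensions, broken pair, ...)."""
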