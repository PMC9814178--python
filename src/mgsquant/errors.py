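"""Exception hierarchy shared across the package."""


class MgsQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MgsQuantError):
    """A configuration value violates a stated constraint."""


class DataError(MgsQuantError):
    """Input data violate a precondition (unknown ids, bad shapes, ...)."""


class FormatError(MgsQuantError):
    """A file could not be parsed; carries line context where possible."""
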