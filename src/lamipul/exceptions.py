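"""Exception hierarchy shared across the package."""


class LamipulError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LamipulError):
    """An input file could not be parsed in the declared dialect."""


class ValidationError(LamipulError):
    """Parsed data violates a structural invariant (duplicate ids, bad spans, ...)."""


class UnknownGeneError(LamipulError, KeyError):
    """A gene/protein identifier was not found in the annotation."""


class ConfigError(LamipulError, ValueError):
    """Mutually inconsistent or out-of-range configuration values."""
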