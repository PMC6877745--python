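"""Exception hierarchy shared across the package."""


class BardSpliceError(Exception):
    """Base class for all package errors."""


class ModelError(BardSpliceError):
    """Inconsistent or invalid transcript model / domain map."""


class EventParseError(BardSpliceError):
    """Ungrammatical splicing-event code or r. description."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


class UnresolvableEventError(BardSpliceError):
    """Event has '?' or unnumbered breakpoints and cannot be resolved to coordinates."""


class OutOfScopeError(BardSpliceError):
    """Variant outside the consensus IVS +/-1,2 dinucleotides."""


class InputError(BardSpliceError):
    """Malformed tabular or sequence input."""


class ConfigError(BardSpliceError):
    """Invalid simulation or run configuration."""
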