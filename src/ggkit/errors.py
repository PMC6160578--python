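"""Exception hierarchy shared by all ggkit modules."""


class GgkitError(Exception):
    """Base class for all ggkit errors."""


class ParseError(GgkitError):
    """A text input could not be parsed (malformed row, bad token, ...)."""


class ValidationError(GgkitError):
    """Parsed data violates a structural invariant."""


class SpecError(GgkitError):
    """A simulation or run specification is internally inconsistent."""


class ConfigError(GgkitError):
    """A pipeline configuration is invalid."""
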