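"""Exception types shared across the package."""


class GliopanelError(Exception):
    """Base class for all package errors."""


class ValidationError(GliopanelError, ValueError):
    """An input violated a documented invariant (exit code 1 at the CLI)."""


class ParseError(GliopanelError, ValueError):
    """A file could not be parsed; the message names the offending line."""
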