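"""Exception types shared across the toolkit."""


class ProphagekitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ProphagekitError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ProphagekitError, ValueError):
    """Parsed or constructed data violates a domain invariant."""
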