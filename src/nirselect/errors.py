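"""Exception hierarchy."""


class NirselectError(Exception):
    """Base class for all package errors."""


class ParseError(NirselectError, ValueError):
    """A delimited-text spectra file could not be parsed."""


class ValidationError(NirselectError, ValueError):
    """Inputs violate a documented precondition or invariant."""
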