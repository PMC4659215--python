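"""Exception hierarchy shared across the package."""


class SpecregError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SpecregError):
    """An input is formally valid but carries no usable signal
    (constant intensity image, empty foreground, zero background channel...)."""


class SearchFailureError(SpecregError):
    """The transform search could not produce a usable result."""
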