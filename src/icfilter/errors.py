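"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to its expected on-disk dialect."""


class InputError(ValueError):
    """An input is well-formed but violates a precondition (e.g. too short)."""


class DegenerateComponentError(ValueError):
    """A component time course carries no usable signal (zero variance)."""
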