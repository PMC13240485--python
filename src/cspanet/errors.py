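"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object or weight set is internally inconsistent."""


class InputError(ValueError):
    """An input array or label violates a precondition (shape, range, finiteness)."""
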