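"""Exception types shared across the package."""


class InputError(ValueError):
    """An argument violates a documented precondition."""


class SchemaError(InputError):
    """A file does not conform to the documented CSV/sidecar schema."""


class FitError(RuntimeError):
    """A nonlinear fit failed in a way that cannot be flagged and returned."""
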