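"""Shared exception types."""


class InputError(ValueError):
    """Raised when input data violate a precondition (shape, order, emptiness)."""


class InferenceError(RuntimeError):
    """Raised when a milestone cannot be inferred, e.g. from an unconverged fit."""
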