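"""Exception hierarchy shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal.

    Raised e.g. for a constant image (nothing to normalize) or a
    contrast-free femoral-head region (no intensity split exists).
    """


class NoFemoralHeadError(ValueError):
    """The femoral-head mask is empty, so head-restricted analysis is impossible."""
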