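"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


class DegenerateClusterError(InputError):
    """Raised when a clustering problem has fewer distinct points than clusters."""


class MulticollinearityError(InputError):
    """Raised when a regression design matrix is rank deficient."""
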