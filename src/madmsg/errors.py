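"""Exception types shared across the package."""


class DataValidationError(ValueError):
    """Raised when input data violate a documented contract.

    CLI entry points map this to exit code 2; any other exception is an
    unexpected failure (exit code 1).
    """
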