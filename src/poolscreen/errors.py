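"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a structural contract (bad library row,
    malformed sample sheet, inconsistent count matrix, invalid configuration)."""


class FastqParseError(ValueError):
    """Raised for malformed or truncated FASTQ input; carries the index of the
    offending record."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index
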