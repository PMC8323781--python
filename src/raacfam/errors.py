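"""Exception hierarchy for raacfam.

All validation failures raise a subclass of :class:`RaacfamError` so callers
(and the CLI) can distinguish user-input problems from genuine bugs.
"""


class RaacfamError(Exception):
    """Base class for all raacfam errors."""


class SchemeError(RaacfamError):
    """Invalid reduction-scheme definition (bad partition, duplicate letter...)."""


class SchemeFileError(RaacfamError):
    """Malformed scheme-library file; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class SequenceError(RaacfamError):
    """Problem with an input sequence (non-canonical residue, empty result...)."""


class TooShortError(SequenceError):
    """Sequence shorter than the k-mer order; carries the sequence id."""

    def __init__(self, seq_id: str, length: int, k: int):
        self.seq_id = seq_id
        self.length = length
        self.k = k
        super().__init__(
            f"sequence {seq_id!r} has length {length} < k={k}; cannot extract k-mers"
        )


class DatasetError(RaacfamError):
    """Dataset-level failure (empty class, unreadable file, single-class labels)."""


class ConfigError(RaacfamError):
    """Invalid configuration value (k out of range, empty grid, bad CV folds...)."""
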