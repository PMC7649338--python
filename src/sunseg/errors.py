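"""Exception hierarchy used across the package."""


class SunsegError(Exception):
    """Base class for all package errors."""


class FormatError(SunsegError):
    """Unreadable or unsupported image/label file."""


class ShapeError(SunsegError):
    """Array shapes incompatible with the requested operation."""


class SizeError(SunsegError):
    """An input is too small/large for the requested operation."""


class CoverageError(SunsegError):
    """Stitching pieces do not cover the output canvas."""


class GenerationError(SunsegError):
    """Synthetic scene placement failed after bounded retries."""


class DataError(SunsegError):
    """Empty or inconsistent dataset/input collection."""


class DivergenceError(SunsegError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None, history=None):
        super().__init__(message)
        self.epoch = epoch
        self.history = history


class ConfigError(SunsegError):
    """Invalid or missing configuration."""
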