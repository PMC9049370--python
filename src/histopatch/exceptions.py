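"""Exception types shared across the pipeline stages."""


class HistopatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HistopatchError, ValueError):
    """A file exists but cannot be decoded as the expected format."""


class DimensionError(HistopatchError, ValueError):
    """Array shapes or lengths are inconsistent with the operation."""


class DegenerateInputError(HistopatchError, ValueError):
    """The input carries no usable signal for this stage (e.g. a blank
    image with no stained pixels, or no foreground markers found)."""


class PackingError(HistopatchError, RuntimeError):
    """Synthetic scene generation could not place the requested nuclei
    under the overlap constraint within the retry budget."""


class ConfigError(HistopatchError, ValueError):
    """A configuration value violates the schema or an invariant."""


class StageError(HistopatchError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
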