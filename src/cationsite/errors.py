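"""Exception hierarchy shared across the package."""


class CationSiteError(Exception):
    """Base class for all package errors."""


class ParseError(CationSiteError):
    """A structure or trajectory file could not be parsed.

    Carries the offending line number (1-based) when known.
    """

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class EmptyInputError(CationSiteError):
    """An input contained no usable records (e.g. a PDB with zero atoms)."""


class FrameMismatchError(CationSiteError):
    """A frame's atom count does not match the topology."""

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        if frame is not None:
            message = f"{message} (frame {frame})"
        super().__init__(message)


class ConfigurationError(CationSiteError):
    """Invalid analysis parameters or an inconsistent run configuration."""


class MergeError(CationSiteError):
    """Tables with incompatible keys or parameters cannot be merged."""


class NormalizationError(CationSiteError):
    """IV normalization reference missing from a recording set."""
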