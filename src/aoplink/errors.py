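"""Exception hierarchy shared across the package.

All data-level failures derive from :class:`AoplinkError` so callers (and the
command-line layer) can distinguish bad input from programming errors.
"""


class AoplinkError(Exception):
    """Base class for all data/stage errors raised by aoplink."""


class ParseError(AoplinkError):
    """A document could not be parsed (malformed XML, wrong dialect, missing ids)."""


class FormatError(AoplinkError):
    """A tabular input violates its declared format (missing columns, bad namespace)."""


class StageError(AoplinkError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
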