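"""Exception taxonomy shared by the whole pipeline.

Three classes so the command line can map failures to distinct exit codes:
bad arguments (2), bad data (3), bad I/O (4).
"""


class ArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DataError(ValueError):
    """Input data are structurally valid but statistically unusable
    (e.g. a constant seed series, an all-censored run)."""


class InputOutputError(OSError):
    """A required file or directory is missing or unreadable."""
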