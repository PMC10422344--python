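"""Exception hierarchy shared by all pipeline stages."""


class GanaugError(Exception):
    """Base class for all package errors."""


class ParameterError(GanaugError, ValueError):
    """A parameter or geometry constraint was violated."""


class ConfigError(GanaugError, ValueError):
    """An invalid configuration value; message carries the config path."""


class DegenerateInputError(GanaugError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant image)."""


class EmptyForegroundError(GanaugError, ValueError):
    """A binary mask required to have foreground pixels is empty."""


class FormatError(GanaugError, ValueError):
    """A manifest or serialized artifact is malformed."""


class InsufficientClassError(GanaugError, ValueError):
    """A class has too few samples for the requested operation."""


class MisuseError(GanaugError, ValueError):
    """An operation was applied to a split or state it must not touch."""


class UsageError(GanaugError, ValueError):
    """Arguments are inconsistent with the model or operation contract."""


class DataError(GanaugError, ValueError):
    """Training or evaluation data is missing or inconsistent."""


class DivergenceError(GanaugError, RuntimeError):
    """A training loss became non-finite; message carries the step index."""
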