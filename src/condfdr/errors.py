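"""Exception types, distinguished so the CLI can map them to exit codes."""


class CondFdrError(Exception):
    """Base class for package errors."""


class ConfigError(CondFdrError):
    """Invalid configuration or malformed input schema."""

    exit_code = 2


class DataError(CondFdrError):
    """Input data cannot support the requested analysis (e.g. empty pair)."""

    exit_code = 3


class EstimationError(CondFdrError):
    """A statistical estimate cannot be formed (e.g. empty fitting set)."""

    exit_code = 4


class EmptyPairError(DataError):
    """The two traits share no SNPs; the pipeline cannot proceed."""
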