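"""Exception types shared across the package."""


class AsrBenchError(Exception):
    """Base class for package errors."""


class ConfigurationError(AsrBenchError):
    """Invalid parameter value; the message names the offending field."""


class InputError(AsrBenchError):
    """Malformed or inconsistent user-supplied data."""


class AdapterError(AsrBenchError):
    """An aligner adapter failed or returned inconsistent output."""


class SimulationError(AsrBenchError):
    """A simulated replicate reached an unusable state (e.g. extinct sequence)."""
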