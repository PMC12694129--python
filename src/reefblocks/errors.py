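class ReefblocksError(Exception):
    """Base class for package errors."""


class ConfigurationError(ReefblocksError):
    """An invalid configuration value (bad mixture weights, unknown mode...)."""


class DataError(ReefblocksError):
    """A dataset-level problem (empty dataset, id mismatch, split leakage)."""


class ParseError(ReefblocksError):
    """A malformed annotation file; message names the file and line."""


class InputError(ReefblocksError):
    """An invalid numeric input to an operation (degenerate box, bad beta)."""
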