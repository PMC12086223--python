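"""Exception hierarchy for the lexdrift pipeline."""


class LexdriftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LexdriftError, ValueError):
    """An invalid simulation or analysis configuration."""


class TrainingError(LexdriftError, RuntimeError):
    """Embedding training could not proceed (e.g. empty pruned vocabulary)."""


class VocabularyError(LexdriftError, KeyError):
    """A requested term is missing from a model's vocabulary."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0] if self.args else ""


class BootstrapError(LexdriftError, RuntimeError):
    """Too many bootstrap replicates were discarded."""


class TrendError(LexdriftError, ValueError):
    """A trend fit was requested on degenerate input."""
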