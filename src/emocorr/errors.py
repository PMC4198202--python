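"""Exception hierarchy for the pipeline."""


class EmocorrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmocorrError):
    """Invalid configuration value (bad model name, threshold < 1, ...)."""


class GenerationError(EmocorrError):
    """Synthetic-data generation failed (e.g. graph never connected)."""


class NoLabelableTweetsError(EmocorrError):
    """No tweet in the corpus carries an unambiguous emoticon label."""


class DegenerateSequenceError(EmocorrError):
    """Correlation is undefined: one of the paired sequences is constant."""


class InsufficientDataError(EmocorrError):
    """Fewer than two pairs available for a correlation stratum."""
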