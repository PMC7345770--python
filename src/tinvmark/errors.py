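"""Exception hierarchy for the tinvmark pipeline."""


class TinvmarkError(Exception):
    """Base class for all tinvmark errors."""


class ConfigurationError(TinvmarkError):
    """A configuration object violates its invariants.

    The message always names the offending field.
    """


class ValidationError(TinvmarkError):
    """Input data violate a contract (shape, vocabulary, labels, ...)."""


class PipelineError(TinvmarkError):
    """A pipeline stage failed; the message names the stage and entity."""
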