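"""Exception hierarchy.

Every error raised by the library derives from :class:`EmbedFuseError` so
callers can catch the whole family with one clause.
"""


class EmbedFuseError(Exception):
    """Base class for all library errors."""


class DuplicateModelError(EmbedFuseError):
    """A model name was registered twice."""


class UnknownModelError(EmbedFuseError):
    """A model name is not present in the registry."""


class DimensionMismatchError(EmbedFuseError):
    """A provider returned a matrix whose width differs from the declared dim."""


class AlignmentError(EmbedFuseError):
    """Sample IDs of two embedding blocks disagree in content or order."""


class ProviderError(EmbedFuseError):
    """A provider callable failed; the model name is attached to the message."""


class CacheIntegrityError(EmbedFuseError):
    """A cached array and its manifest disagree (corruption, truncation)."""


class ConfigError(EmbedFuseError):
    """An invalid configuration field; the message names the field."""


class UndefinedMetricError(EmbedFuseError):
    """A metric is undefined on the given input (e.g. AUC with one class)."""


class TrainingDivergenceError(EmbedFuseError):
    """Attention-fusion training produced a non-finite loss."""
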