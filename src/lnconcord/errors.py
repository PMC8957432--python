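"""Exception hierarchy.

All package errors derive from :class:`LNConcordError` so callers (and the
CLI) can catch everything in one place while tests discriminate precisely.
"""


class LNConcordError(Exception):
    """Base class for every error raised by lnconcord."""


class DomainError(LNConcordError, ValueError):
    """A value is outside the mathematical domain of an operation
    (negative distance, non-positive node size, negative count, ...)."""


class FormatError(LNConcordError, ValueError):
    """A file does not conform to its declared schema; the message names
    the offending line or column."""


class VocabularyError(LNConcordError, ValueError):
    """A label is not in a closed vocabulary; the message lists the
    allowed values."""


class IntegrityError(LNConcordError, ValueError):
    """Referential integrity between cohort tables is violated
    (orphan patient ids, unresolvable station codes, ...)."""


class ConfigError(LNConcordError, ValueError):
    """A simulation or CLI configuration is invalid."""


class CalibrationInfeasibleError(LNConcordError, ValueError):
    """The requested odds-ratio targets cannot be realised as a proper
    probability vector under the given prevalences and overall rate."""
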