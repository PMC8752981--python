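"""Exception types shared across the package."""


class FeatsigError(Exception):
    """Base class for all featsig errors."""


class InvalidMutationError(FeatsigError, ValueError):
    """A mutation record violates its preconditions (non-ACGT base, ref == alt, ...)."""


class EmptyInputError(FeatsigError, ValueError):
    """Every input record was rejected, leaving nothing to analyse."""


class UndefinedNormalizationError(FeatsigError, ValueError):
    """An all-zero spectrum cannot be normalized to frequencies."""


class DimensionError(FeatsigError, ValueError):
    """Channel dimensions of two objects do not match."""


class SampleExcluded(FeatsigError):
    """A sample fails the mutation-count gate for signature analysis."""


class DegenerateStratificationError(FeatsigError, ValueError):
    """A feature cannot split the cohort into two nonempty groups."""


class EmptySignatureError(FeatsigError, ValueError):
    """The differential between groups is identically zero."""


class SingularPairError(FeatsigError, ValueError):
    """The positive/negative signature pair is linearly dependent."""


class UndefinedSimilarityError(FeatsigError, ValueError):
    """Cosine similarity is undefined for a zero-norm vector."""


class UndefinedCorrelationError(FeatsigError, ValueError):
    """Pearson correlation is undefined (zero variance or too few pairs)."""


class InsufficientDataError(FeatsigError, ValueError):
    """A group is too small for the requested statistical comparison."""


class ConfigError(FeatsigError, ValueError):
    """A simulation configuration is infeasible or inconsistent."""


class RetryExhaustedError(FeatsigError, RuntimeError):
    """Rejection sampling failed to satisfy a constraint within the attempt budget."""
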