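"""Exception types shared across the package."""


class SaliencyError(Exception):
    """Base class for salicsd-specific failures."""


class ImageLoadError(SaliencyError):
    """An image file could not be read or decoded."""


class FixationParseError(SaliencyError):
    """A fixation CSV is malformed; the message names the offending row."""


class DegenerateDictionaryError(SaliencyError):
    """Patch data carries no variance, so no basis can be learned.

    Callers in the saliency pipeline map this to an all-zero map.
    """


class EmbeddingError(SaliencyError):
    """Cholesky factorization failed even after diagonal jitter escalation."""


class UndefinedScoreError(SaliencyError):
    """A rank statistic was requested on an empty positive or negative set."""
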