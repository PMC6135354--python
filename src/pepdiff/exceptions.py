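"""Exception hierarchy for pipeline errors.

Every error raised by pepdiff derives from :class:`PepdiffError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class PepdiffError(Exception):
    """Base class for all pepdiff errors."""


class FormatError(PepdiffError):
    """A delimited-text input does not match the documented table contract."""


class IntegrityError(PepdiffError):
    """Internally inconsistent data (duplicate keys, mismatched protein sets)."""


class EmptyTableError(PepdiffError):
    """An operation received or produced a table with no usable rows."""


class DegenerateSampleError(PepdiffError):
    """A sample column has no present values, so no center can be computed."""


class DegenerateResponseError(PepdiffError):
    """The response vector is constant; no discriminant direction exists."""


class RankError(PepdiffError):
    """Requested number of latent components exceeds what the data support."""


class FoldError(PepdiffError):
    """Cross-validation folds cannot be built with both classes in each fold."""


class ConfigError(PepdiffError):
    """A configuration value violates its documented range or invariant."""
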