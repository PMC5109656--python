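"""Exception hierarchy shared across the package."""


class FgiTyperError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FgiTyperError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(FgiTyperError):
    """Input data violates a documented invariant."""


class UndefinedContentError(FgiTyperError):
    """G+C content requested for a sequence with no unambiguous bases."""


class AnchorsNotFoundError(FgiTyperError):
    """No qualifying flaA2/flaG anchor pair was found on a single contig."""

    def __init__(self, message, near_misses=None):
        super().__init__(message)
        #: list of (feature_id, anchor_name, identity_pct, coverage_pct)
        self.near_misses = near_misses or []


class MalformedLocusError(FgiTyperError):
    """Anchor genes overlap or are mis-ordered."""


class ConfigurationError(FgiTyperError):
    """A configuration value or reference set is unusable."""
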