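"""Exception types shared across the package."""


class KaryocoiError(Exception):
    """Base class for all package errors."""


class ValidationError(KaryocoiError, ValueError):
    """Invalid input data (bad measurement, malformed table, odd counts...)."""


class NoOverlapError(KaryocoiError):
    """Two aligned sequences share no comparable sites after deletion."""


class OutgroupError(KaryocoiError):
    """Outgroup taxa missing from the tree or not separable from the ingroup."""
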