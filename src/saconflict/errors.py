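"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
DegenerateDataError -> 3.
"""


class SaconflictError(Exception):
    """Base class for all package errors."""


class ValidationError(SaconflictError, ValueError):
    """Input violates a documented contract (schema, sign, range, ...)."""


class DomainError(SaconflictError, ValueError):
    """A formula is evaluated outside its mathematical domain."""


class InsufficientDataError(SaconflictError, ValueError):
    """Too few records to carry out the requested computation."""


class DegenerateDataError(SaconflictError, ValueError):
    """Data admit no informative test (e.g. an all-identical pooled sample)."""
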