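"""Exception hierarchy shared across the package."""

from .codebooks import CodeBookError, ConsistencyError, KeyValidationError


class TrajstoreError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(TrajstoreError, ValueError):
    """Input rejected before any write occurred."""


class IntegrityError(TrajstoreError):
    """A write was refused because it would corrupt cross-tier linkage,
    or stored data violate the standard's invariants."""


class NotFoundError(TrajstoreError, LookupError):
    """A key, simulation, table, or snapshot does not exist."""


__all__ = [
    "TrajstoreError", "ValidationError", "IntegrityError", "NotFoundError",
    "CodeBookError", "ConsistencyError", "KeyValidationError",
]
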