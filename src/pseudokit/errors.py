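"""Exception hierarchy for pseudokit.

Every error carries a short machine-readable ``code`` so that the service
layer can map it onto a response status and the audit trail can record the
outcome of failed operations.
"""

from __future__ import annotations


class PseudokitError(Exception):
    """Base class for all domain-level errors raised by pseudokit."""

    code = "error"

    def __init__(self, message: str = "", **context):
        super().__init__(message or self.code)
        self.context = context


class ValidationError(PseudokitError):
    code = "validation-error"


class DuplicateNameError(PseudokitError):
    code = "duplicate-name"


class NotFoundError(PseudokitError):
    code = "not-found"


class UnknownDomainError(NotFoundError):
    code = "unknown-domain"


class UnknownAttributeError(PseudokitError):
    code = "unknown-attribute"


class UnknownAlgorithmError(PseudokitError):
    code = "unknown-algorithm"


class PrivilegeError(PseudokitError):
    code = "privilege-violation"


class UnauthorizedError(PseudokitError):
    code = "unauthorized"


class DomainNotEmptyError(PseudokitError):
    code = "domain-not-empty"


class CharacterNotInAlphabetError(PseudokitError):
    code = "character-not-in-alphabet"


class CounterOverflowError(PseudokitError):
    code = "counter-overflow"


class ExhaustedRetriesError(PseudokitError):
    code = "exhausted-retries"


class HashCollisionError(PseudokitError):
    code = "hash-collision"


class UniquenessError(PseudokitError):
    code = "uniqueness-violation"


class ExpiredError(PseudokitError):
    code = "expired"


class CapacityError(PseudokitError):
    """Raised when a namespace cannot hold the requested number of pseudonyms."""

    code = "capacity-too-small"


class DomainOverfullError(PseudokitError):
    code = "domain-overfull"


class EmptySeriesError(PseudokitError):
    code = "empty-series"
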