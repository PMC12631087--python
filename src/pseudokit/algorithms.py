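"""Pseudonym generation: salted hashes, random strings, counters, check digits.

Nine generation algorithms are supported.  Six are salted hash functions
(MD5, SHA1, SHA2/SHA-256, SHA3/SHA3-512, BLAKE3, xxHash64) whose hex digests
span 16-128 characters (64-512 bits); the remaining three are a per-domain
consecutive counter and uniform random strings/numbers of a configured length.
Random and counter pseudonyms can carry a trailing Luhn mod N check character
and are padded or cut to the configured length; hash digests are left
untouched unless length or check digits were explicitly configured for the
domain, since hashes typically feed automated pipelines while short
check-digited codes are meant for humans.

Collisions: random algorithms retry up to ``m`` times against a caller-
supplied uniqueness predicate; hash and counter algorithms are deterministic
or sequential and are attempted exactly once.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass
from typing import Callable, Optional

from ._blake3 import blake3_hexdigest
from ._xxhash import xxh64_hexdigest
from .domains import Alphabet, BUILTIN_ALPHABETS, DomainConfig, HASH_ALGORITHMS
from .errors import (
    CharacterNotInAlphabetError,
    CounterOverflowError,
    ExhaustedRetriesError,
    HashCollisionError,
    UnknownAlgorithmError,
    ValidationError,
)

_HEX = BUILTIN_ALPHABETS["hexadecimal"]


@dataclass(frozen=True)
class Pseudonym:
    """A formatted pseudonym: prefix + body (+ optional check character)."""

    body: str
    check_char: Optional[str] = None
    prefix: str = ""

    @property
    def full(self) -> str:
        return self.prefix + self.body + (self.check_char or "")


@dataclass(frozen=True)
class GenerationRequest:
    """One generation task: an identifier, the effective domain config and a
    predicate telling whether a candidate pseudonym is still unused."""

    identifier: str
    config: DomainConfig
    uniqueness_check: Callable[[str], bool] = lambda candidate: True

    def __post_init__(self):
        if not self.identifier:
            raise ValidationError("identifier must be non-empty")


# ---------------------------------------------------------------------------
# Hashing

def hash_digest(identifier: str, salt: str, algorithm: str) -> str:
    """Lowercase hex digest of the salted identifier (UTF-8 of id + salt)."""
    data = (identifier + salt).encode("utf-8")
    if algorithm == "md5":
        return hashlib.md5(data).hexdigest()
    if algorithm == "sha1":
        return hashlib.sha1(data).hexdigest()
    if algorithm == "sha2":
        return hashlib.sha256(data).hexdigest()
    if algorithm == "sha3":
        return hashlib.sha3_512(data).hexdigest()
    if algorithm == "blake3":
        return blake3_hexdigest(data)
    if algorithm == "xxhash":
        return xxh64_hexdigest(data)
    raise UnknownAlgorithmError(f"unknown hash algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Random bodies and counters

def random_body(length: int, alphabet: Alphabet, rng=None) -> str:
    """Uniform random string of ``length`` characters from ``alphabet``.

    ``rng`` may be any object with a ``choice`` method (e.g. random.Random
    for reproducible tests); the default draws from the OS entropy pool.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    chooser = rng.choice if rng is not None else secrets.choice
    return "".join(chooser(alphabet.characters) for _ in range(length))


def next_counter(state: int, length: int, padding_char: str = "0"):
    """Advance a consecutive-number domain: returns (new_state, rendering).

    The counter starts at 1 (state 0 yields "00000001" at length 8) and the
    decimal rendering is left-padded to ``length``; exceeding the width is a
    counter-overflow, never a truncation.
    """
    if state < 0:
        raise ValidationError("counter state must be non-negative")
    new_state = state + 1
    rendered = str(new_state)
    if len(rendered) > length:
        raise CounterOverflowError(
            f"counter value {new_state} does not fit in {length} characters")
    return new_state, rendered.rjust(length, padding_char)


# ---------------------------------------------------------------------------
# Luhn mod N check characters

def _fold(value: int, n: int) -> int:
    # digit sum of a doubled value in base n (at most two digits)
    return value // n + value % n


def luhn_mod_n_check_char(payload: str, alphabet: Alphabet) -> str:
    """Check character making the Luhn mod N sum of payload+check vanish.

    Walking the payload right to left, every value is doubled (with base-N
    digit-sum folding) starting at the rightmost character, because the check
    character itself will occupy the undoubled final position.
    """
    n = alphabet.size
    total = 0
    factor = 2
    for char in reversed(payload):
        if char not in alphabet:
            raise CharacterNotInAlphabetError(
                f"character {char!r} not in alphabet {alphabet.name!r}")
        total += _fold(factor * alphabet.index(char), n)
        factor = 1 if factor == 2 else 2
    return alphabet.characters[(n - total % n) % n]


def validate_check_digit(candidate: str, alphabet: Alphabet) -> bool:
    """True iff the last character is the Luhn mod N check of the rest."""
    if len(candidate) < 2:
        raise ValidationError("candidate must have payload plus check character")
    if candidate[-1] not in alphabet:
        raise CharacterNotInAlphabetError(
            f"character {candidate[-1]!r} not in alphabet {alphabet.name!r}")
    return luhn_mod_n_check_char(candidate[:-1], alphabet) == candidate[-1]


# ---------------------------------------------------------------------------
# Formatting and dispatch

def format_pseudonym(raw: str, config: DomainConfig,
                     alphabet: Optional[Alphabet] = None,
                     apply_length: bool = True,
                     apply_check: bool = True) -> Pseudonym:
    """Pad/cut ``raw`` to the configured length, prefix it, append check char.

    Padding is on the left with the configured padding character; cutting
    keeps the leftmost characters.  The check character is computed over the
    prefix-less body (the prefix is routing metadata, not payload).
    """
    if not raw:
        raise ValidationError("raw pseudonym must be non-empty")
    body = raw
    if apply_length:
        if len(body) < config.length:
            body = body.rjust(config.length, config.padding_char)
        elif len(body) > config.length:
            body = body[:config.length]
    check = None
    if apply_check and config.check_digit:
        check = luhn_mod_n_check_char(body, alphabet or config.alphabet)
    return Pseudonym(body=body, check_char=check, prefix=config.prefix)


def generate(request: GenerationRequest, rng=None) -> Pseudonym:
    """Generate a pseudonym for the request's identifier.

    Random algorithms draw fresh candidates until the uniqueness check
    passes, trying at most ``config.retries`` times in total.  Hash
    algorithms are deterministic and tried once — an occupied candidate is a
    hash collision.  The counter is sequential and tried once.
    """
    cfg = request.config
    unique = request.uniqueness_check

    if cfg.algorithm in HASH_ALGORITHMS:
        digest = hash_digest(request.identifier, cfg.salt, cfg.algorithm)
        pseudonym = format_pseudonym(
            digest, cfg, alphabet=_HEX,
            apply_length=cfg.length_explicit,
            apply_check=cfg.check_digit_explicit)
        if not unique(pseudonym.full):
            raise HashCollisionError(
                f"hash pseudonym for {request.identifier!r} already taken")
        return pseudonym

    if cfg.algorithm == "consecutive":
        new_state, rendered = next_counter(cfg.counter_state, cfg.length,
                                           cfg.padding_char)
        cfg.counter_state = new_state
        pseudonym = format_pseudonym(rendered, cfg,
                                     alphabet=BUILTIN_ALPHABETS["digits"])
        if not unique(pseudonym.full):
            raise HashCollisionError(
                f"counter pseudonym {pseudonym.full!r} already taken")
        return pseudonym

    if cfg.algorithm in ("random_string", "random_number"):
        alphabet = (BUILTIN_ALPHABETS["digits"]
                    if cfg.algorithm == "random_number" else cfg.alphabet)
        for _attempt in range(cfg.retries):
            body = random_body(cfg.length, alphabet, rng)
            pseudonym = format_pseudonym(body, cfg, alphabet=alphabet)
            if unique(pseudonym.full):
                return pseudonym
        raise ExhaustedRetriesError(
            f"no unused pseudonym found in {cfg.retries} attempts")

    raise UnknownAlgorithmError(f"unknown algorithm {cfg.algorithm!r}")


__all__ = [
    "Pseudonym", "GenerationRequest", "hash_digest", "random_body",
    "next_counter", "luhn_mod_n_check_char", "validate_check_digit",
    "format_pseudonym", "generate",
]
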