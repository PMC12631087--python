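"""Hierarchical pseudonym domains with attribute inheritance.

A *domain* is a named pseudonym space carrying the full generation
configuration (algorithm, alphabet, length, check digits, retries, capacity
target, validity period, ...).  Domains nest into trees — a study with visits,
a visit with data modalities — and child domains inherit configuration values
from their parent unless a value is explicitly overwritten.  Every inheritable
attribute carries a flag recording which case applies, and updates can be
propagated down the tree, descending only into subtrees whose flag for that
attribute is still *inherited*.

This module owns the in-memory domain tree and its semantics; durable storage
and audit are layered on top by :mod:`pseudokit.engine`.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Dict, Iterable, List, Optional, Set, Tuple

from . import sizing
from .errors import (
    DomainNotEmptyError,
    DuplicateNameError,
    PrivilegeError,
    UnknownAlgorithmError,
    UnknownAttributeError,
    UnknownDomainError,
    ValidationError,
)

ALGORITHMS = (
    "md5", "sha1", "sha2", "sha3", "blake3", "xxhash",
    "consecutive", "random_number", "random_string",
)
HASH_ALGORITHMS = frozenset(ALGORITHMS[:6])


@dataclass(frozen=True)
class Alphabet:
    """A named, ordered set of distinct characters."""

    name: str
    characters: str

    def __post_init__(self):
        if len(set(self.characters)) != len(self.characters):
            raise ValidationError(f"alphabet {self.name!r} has repeated characters")
        if len(self.characters) < 2:
            raise ValidationError("alphabet needs at least 2 characters")

    @property
    def size(self) -> int:
        return len(self.characters)

    def index(self, char: str) -> int:
        return self.characters.index(char)

    def __contains__(self, char: str) -> bool:
        return char in self.characters


_DIGITS = "0123456789"
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: The five built-in alphabets.  "reduced_alphanumeric" drops B, I, O and S
#: because of their visual similarity to 8, 1, 0 and 5.
BUILTIN_ALPHABETS: Dict[str, Alphabet] = {
    "hexadecimal": Alphabet("hexadecimal", _DIGITS + "abcdef"),
    "digits": Alphabet("digits", _DIGITS),
    "letters": Alphabet("letters", _LETTERS),
    "alphanumeric": Alphabet("alphanumeric", _LETTERS + _DIGITS),
    "reduced_alphanumeric": Alphabet(
        "reduced_alphanumeric",
        "".join(c for c in _LETTERS if c not in "BIOS") + _DIGITS),
}


def get_alphabet(name_or_alphabet) -> Alphabet:
    if isinstance(name_or_alphabet, Alphabet):
        return name_or_alphabet
    try:
        return BUILTIN_ALPHABETS[name_or_alphabet]
    except KeyError:
        raise UnknownAttributeError(f"unknown alphabet {name_or_alphabet!r}")


@dataclass(frozen=True)
class ValidityPeriod:
    """Half-open time interval [start, end); None means unbounded."""

    start: Optional[datetime] = None
    end: Optional[datetime] = None

    def __post_init__(self):
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValidationError("validity start must not exceed end")

    def contains(self, at: datetime) -> bool:
        if self.start is not None and at < self.start:
            return False
        if self.end is not None and at >= self.end:
            return False
        return True


#: Attributes a child domain may inherit from its parent.  The two bounds of
#: the validity period inherit independently.  The *_explicit markers travel
#: with their base attribute so that hash-output formatting rules survive
#: inheritance.
INHERITABLE_ATTRIBUTES = (
    "algorithm", "alphabet", "length", "padding_char", "prefix",
    "check_digit", "retries", "capacity_target", "success_threshold",
    "validity.start", "validity.end",
)

#: Attributes that may only be set through the privileged create/update calls.
PRIVILEGED_ATTRIBUTES = frozenset({"salt", "length", "padding_char"})

#: Root-domain defaults: random 10-character strings over the letters
#: alphabet (length auto-computed from q=1e8, m=3, T=0.99999998), with check
#: digits appended.
ROOT_DEFAULTS = {
    "algorithm": "random_string",
    "alphabet": "letters",
    "padding_char": "0",
    "prefix": "",
    "check_digit": True,
    "retries": 3,
    "capacity_target": 100_000_000,
    "success_threshold": 0.99999998,
    "validity.start": None,
    "validity.end": None,
}


@dataclass
class DomainConfig:
    """One node of the domain tree, with materialised attribute values.

    ``inherited`` maps each inheritable attribute name to True (value copied
    from the parent and still tracking it) or False (explicitly overwritten
    or domain-local).
    """

    name: str
    parent: Optional[str] = None
    algorithm: str = "random_string"
    alphabet: Alphabet = field(default_factory=lambda: BUILTIN_ALPHABETS["letters"])
    length: int = 10
    padding_char: str = "0"
    prefix: str = ""
    check_digit: bool = True
    salt: str = ""
    retries: int = 3
    capacity_target: int = 100_000_000
    success_threshold: float = 0.99999998
    validity: ValidityPeriod = field(default_factory=ValidityPeriod)
    counter_state: int = 0
    inherited: Dict[str, bool] = field(default_factory=dict)
    length_explicit: bool = False
    check_digit_explicit: bool = False

    def get_attribute(self, attribute: str):
        if attribute == "validity.start":
            return self.validity.start
        if attribute == "validity.end":
            return self.validity.end
        if attribute in ("salt", "counter_state") or attribute in INHERITABLE_ATTRIBUTES:
            return getattr(self, attribute)
        raise UnknownAttributeError(f"unknown attribute {attribute!r}")

    def set_attribute(self, attribute: str, value) -> None:
        if attribute == "validity.start":
            self.validity = ValidityPeriod(start=value, end=self.validity.end)
        elif attribute == "validity.end":
            self.validity = ValidityPeriod(start=self.validity.start, end=value)
        elif attribute == "alphabet":
            self.alphabet = get_alphabet(value)
        elif attribute in INHERITABLE_ATTRIBUTES or attribute in ("salt", "counter_state"):
            setattr(self, attribute, value)
        else:
            raise UnknownAttributeError(f"unknown attribute {attribute!r}")


class DomainTree:
    """Mutable forest of domains implementing inheritance semantics.

    All operations are pure in-memory bookkeeping; persistence, auditing and
    record-level propagation are the engine's responsibility.
    """

    def __init__(self):
        self._domains: Dict[str, DomainConfig] = {}

    # -- basic access -----------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._domains

    def names(self) -> List[str]:
        return list(self._domains)

    def get(self, name: str) -> DomainConfig:
        try:
            return self._domains[name]
        except KeyError:
            raise UnknownDomainError(f"domain {name!r} does not exist")

    def children(self, name: str) -> List[str]:
        return [d.name for d in self._domains.values() if d.parent == name]

    def ancestors_or_self(self, name: str) -> List[str]:
        """Chain from the domain up to its root (cycle-checked)."""
        chain, seen = [], set()
        cur: Optional[str] = name
        while cur is not None:
            if cur in seen:
                raise ValidationError(f"parent cycle at {cur!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.get(cur).parent
        return chain

    def subtree(self, name: str) -> List[str]:
        self.get(name)
        out, stack = [], [name]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.children(cur))
        return out

    def find_common_ancestor(self, d1: str, d2: str) -> Optional[str]:
        """Deepest domain that is an ancestor-or-self of both, else None."""
        chain1 = self.ancestors_or_self(d1)
        chain2 = set(self.ancestors_or_self(d2))
        for name in chain1:  # chain1 is ordered deepest-first
            if name in chain2:
                return name
        return None

    # -- create -----------------------------------------------------------

    def create(self, name: str, spec: Optional[dict] = None,
               parent: Optional[str] = None, privileged: bool = False) -> DomainConfig:
        """Create a domain, inheriting unspecified attributes from its parent.

        ``spec`` maps attribute names (dotted form for validity bounds) to
        explicit values.  Privileged-only attributes (salt, length,
        padding_char) require ``privileged=True``.  A missing length is
        inherited from the parent, or — for roots, or when a capacity target
        is explicitly given — auto-computed so that the fill-success
        probability of ``capacity_target`` pseudonyms exceeds
        ``success_threshold``.
        """
        spec = dict(spec or {})
        if name in self._domains:
            raise DuplicateNameError(f"domain {name!r} already exists")
        if parent is not None:
            self.get(parent)
        if not privileged:
            bad = PRIVILEGED_ATTRIBUTES & set(spec)
            if bad:
                raise PrivilegeError(f"attributes {sorted(bad)} require privilege")
        if "algorithm" in spec and spec["algorithm"] not in ALGORITHMS:
            raise UnknownAlgorithmError(f"unknown algorithm {spec['algorithm']!r}")

        cfg = DomainConfig(name=name, parent=parent)
        parent_cfg = self._domains[parent] if parent else None

        for attr in INHERITABLE_ATTRIBUTES:
            if attr == "length" and "length" not in spec:
                continue  # handled below
            if attr in spec:
                cfg.set_attribute(attr, spec[attr])
                cfg.inherited[attr] = False
            elif parent_cfg is not None:
                cfg.set_attribute(attr, parent_cfg.get_attribute(attr))
                cfg.inherited[attr] = True
            else:
                cfg.set_attribute(attr, ROOT_DEFAULTS[attr])
                cfg.inherited[attr] = False

        cfg.length_explicit = "length" in spec
        cfg.check_digit_explicit = "check_digit" in spec
        if parent_cfg is not None and "check_digit" not in spec:
            cfg.check_digit_explicit = parent_cfg.check_digit_explicit

        if "length" in spec:
            cfg.length = int(spec["length"])
            cfg.inherited["length"] = False
        elif parent_cfg is not None and "capacity_target" not in spec:
            cfg.length = parent_cfg.length
            cfg.inherited["length"] = True
            cfg.length_explicit = parent_cfg.length_explicit
        else:
            cfg.length = sizing.required_length(
                cfg.capacity_target, cfg.retries, cfg.success_threshold,
                cfg.alphabet.size)
            cfg.inherited["length"] = False
        if cfg.length < 1:
            raise ValidationError("length must be positive")

        # salt is domain-local: never inherited, generated when absent
        cfg.salt = spec.get("salt") or secrets.token_hex(16)
        cfg.counter_state = int(spec.get("counter_state", 0))
        self._domains[name] = cfg
        return cfg

    # -- update / propagation ---------------------------------------------

    def update(self, name: str, changes: dict, propagate: bool = False,
               privileged: bool = False) -> Dict[str, Set[str]]:
        """Apply attribute changes; optionally propagate to inheriting children.

        Returns ``{domain_name: {changed attributes}}`` for every touched
        domain (the target plus, when propagating, every descendant whose
        flag for a changed attribute was still *inherited*; an overwritten
        flag blocks descent into that subtree for that attribute).
        """
        cfg = self.get(name)
        changes = dict(changes)
        if not privileged:
            bad = PRIVILEGED_ATTRIBUTES & set(changes)
            if bad:
                raise PrivilegeError(f"attributes {sorted(bad)} require privilege")
        unknown = set(changes) - set(INHERITABLE_ATTRIBUTES)
        if unknown:
            raise UnknownAttributeError(f"unknown attributes {sorted(unknown)}")
        if "algorithm" in changes and changes["algorithm"] not in ALGORITHMS:
            raise UnknownAlgorithmError(f"unknown algorithm {changes['algorithm']!r}")

        affected: Dict[str, Set[str]] = {name: set(changes)}
        for attr, value in changes.items():
            cfg.set_attribute(attr, value)
            cfg.inherited[attr] = False
            if attr == "length":
                cfg.length_explicit = True
            if attr == "check_digit":
                cfg.check_digit_explicit = True
            if propagate:
                self._propagate(name, attr, value, affected)
        return affected

    def _propagate(self, name: str, attr: str, value,
                   affected: Dict[str, Set[str]]) -> None:
        for child_name in self.children(name):
            child = self._domains[child_name]
            if not child.inherited.get(attr, False):
                continue  # overwritten: blocks this subtree
            child.set_attribute(attr, value)
            affected.setdefault(child_name, set()).add(attr)
            self._propagate(child_name, attr, value, affected)

    # -- other operations ---------------------------------------------------

    def get_attribute(self, name: str, attribute: str,
                      privileged: bool = False) -> Tuple[object, bool]:
        """Return (materialised value, inherited flag) for one attribute."""
        cfg = self.get(name)
        if attribute == "salt":
            if not privileged:
                raise PrivilegeError("salt is readable only by privileged callers")
            return cfg.salt, False
        value = cfg.get_attribute(attribute)
        return value, cfg.inherited.get(attribute, False)

    def set_salt(self, name: str, salt: str) -> DomainConfig:
        cfg = self.get(name)
        cfg.salt = salt
        return cfg

    def delete(self, name: str) -> None:
        self.get(name)
        if self.children(name):
            raise DomainNotEmptyError(f"domain {name!r} has child domains")
        del self._domains[name]

    # -- import / export ----------------------------------------------------

    def export_config(self, name: str) -> dict:
        """Key/value document for one domain (parent referenced by name)."""
        cfg = self.get(name)
        doc = {
            "name": cfg.name, "parent": cfg.parent,
            "algorithm": cfg.algorithm, "alphabet": cfg.alphabet.name,
            "length": cfg.length, "padding_char": cfg.padding_char,
            "prefix": cfg.prefix, "check_digit": cfg.check_digit,
            "retries": cfg.retries, "capacity_target": cfg.capacity_target,
            "success_threshold": cfg.success_threshold,
            "validity.start": cfg.validity.start.isoformat() if cfg.validity.start else None,
            "validity.end": cfg.validity.end.isoformat() if cfg.validity.end else None,
            "counter_state": cfg.counter_state,
        }
        doc["inherited"] = {a: cfg.inherited.get(a, False) for a in INHERITABLE_ATTRIBUTES}
        return doc


__all__ = [
    "Alphabet", "BUILTIN_ALPHABETS", "get_alphabet", "ValidityPeriod",
    "DomainConfig", "DomainTree", "ALGORITHMS", "HASH_ALGORITHMS",
    "INHERITABLE_ATTRIBUTES", "PRIVILEGED_ATTRIBUTES", "ROOT_DEFAULTS",
]
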