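"""The pseudonymization engine: audited, transactional domain and record CRUD.

This layer composes the in-memory :class:`~pseudokit.domains.DomainTree`
(inheritance semantics) with the sqlite-backed :class:`~pseudokit.store.Database`
(durability, uniqueness, audit).  Every public operation:

* runs inside a transaction (rollback leaves no partial state, including the
  in-memory tree, which is reloaded from the database on failure),
* writes exactly one audit event — also for failed operations, whose outcome
  records the error code (failed lookups are deliberately audited),
* enforces the privilege split between standard and privileged variants.

Creating a pseudonym is idempotent: re-creating an existing
(domain, identifier) pair returns the stored record unchanged, so batch jobs
can safely be re-run.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from . import algorithms
from .domains import DomainConfig, DomainTree, ValidityPeriod, get_alphabet
from .errors import (
    NotFoundError,
    ExpiredError,
    PrivilegeError,
    DomainNotEmptyError,
    PseudokitError,
    UniquenessError,
    ValidationError,
)
from .store import AuditEvent, AuditPolicy, Database, utcnow, _iso, _from_iso


@dataclass(frozen=True)
class PseudonymRecord:
    """One identifier-to-pseudonym link with its own validity period."""

    identifier: str
    pseudonym: str
    domain: str
    validity: ValidityPeriod
    validity_start_inherited: bool
    validity_end_inherited: bool
    created_at: datetime
    updated_at: datetime


def _record_from_row(row: dict) -> PseudonymRecord:
    return PseudonymRecord(
        identifier=row["identifier"], pseudonym=row["pseudonym"],
        domain=row["domain"],
        validity=ValidityPeriod(_from_iso(row["validity_start"]),
                                _from_iso(row["validity_end"])),
        validity_start_inherited=bool(row["validity_start_inherited"]),
        validity_end_inherited=bool(row["validity_end_inherited"]),
        created_at=_from_iso(row["created_at"]),
        updated_at=_from_iso(row["updated_at"]))


class Engine:
    """Facade over the whole service: domains, pseudonyms, audit."""

    def __init__(self, db: Optional[Database] = None,
                 policy: Optional[AuditPolicy] = None,
                 rng: Optional[random.Random] = None):
        self.db = db or Database(policy=policy)
        if policy is not None:
            self.db.policy = policy
        self.tree = DomainTree()
        self.rng = rng  # None -> OS entropy; a seeded Random for reproducibility
        self._load_tree()

    # ------------------------------------------------------------------
    # tree <-> rows

    def _load_tree(self) -> None:
        tree = DomainTree()
        rows = self.db.load_domain_rows()
        by_name = {r["name"]: r for r in rows}
        done: Set[str] = set()

        def add(name: str) -> None:
            if name in done:
                return
            row = by_name[name]
            if row["parent"]:
                add(row["parent"])
            cfg = DomainConfig(
                name=row["name"], parent=row["parent"],
                algorithm=row["algorithm"],
                alphabet=get_alphabet(row["alphabet"]),
                length=row["length"], padding_char=row["padding_char"],
                prefix=row["prefix"], check_digit=bool(row["check_digit"]),
                salt=row["salt"], retries=row["retries"],
                capacity_target=row["capacity_target"],
                success_threshold=row["success_threshold"],
                validity=ValidityPeriod(_from_iso(row["validity_start"]),
                                        _from_iso(row["validity_end"])),
                counter_state=row["counter_state"],
                length_explicit=bool(row["length_explicit"]),
                check_digit_explicit=bool(row["check_digit_explicit"]))
            for attr in ("algorithm", "alphabet", "length", "padding_char",
                         "prefix", "check_digit", "retries", "capacity_target",
                         "success_threshold"):
                cfg.inherited[attr] = bool(row[f"{attr}_inherited"])
            cfg.inherited["validity.start"] = bool(row["validity_start_inherited"])
            cfg.inherited["validity.end"] = bool(row["validity_end_inherited"])
            tree._domains[name] = cfg
            done.add(name)

        for name in by_name:
            add(name)
        self.tree = tree

    def _domain_row(self, cfg: DomainConfig) -> dict:
        row = {
            "name": cfg.name, "parent": cfg.parent,
            "algorithm": cfg.algorithm, "alphabet": cfg.alphabet.name,
            "length": cfg.length, "length_explicit": int(cfg.length_explicit),
            "padding_char": cfg.padding_char, "prefix": cfg.prefix,
            "check_digit": int(cfg.check_digit),
            "check_digit_explicit": int(cfg.check_digit_explicit),
            "salt": cfg.salt, "retries": cfg.retries,
            "capacity_target": cfg.capacity_target,
            "success_threshold": cfg.success_threshold,
            "validity_start": _iso(cfg.validity.start),
            "validity_end": _iso(cfg.validity.end),
            "counter_state": cfg.counter_state,
        }
        for attr in ("algorithm", "alphabet", "length", "padding_char",
                     "prefix", "check_digit", "retries", "capacity_target",
                     "success_threshold"):
            row[f"{attr}_inherited"] = int(cfg.inherited.get(attr, False))
        row["validity_start_inherited"] = int(cfg.inherited.get("validity.start", False))
        row["validity_end_inherited"] = int(cfg.inherited.get("validity.end", False))
        return row

    # ------------------------------------------------------------------
    # audit plumbing

    def _audited(self, operation: str, action: str, domain: Optional[str],
                 actor: str, actor_class: str, work: Callable):
        """Run ``work`` in a transaction with exactly one audit event.

        Success: operation effects and the audit row commit together.
        Domain-level failure: the operation rolls back, then the failure is
        audited (with the error code as outcome) and the error re-raised.
        """
        try:
            with self.db.transaction():
                result = work()
                self.db.record_audit(AuditEvent(
                    utcnow(), actor, actor_class, action, operation, domain,
                    "success"))
                return result
        except PseudokitError as err:
            self._load_tree()
            with self.db.transaction():
                self.db.record_audit(AuditEvent(
                    utcnow(), actor, actor_class, action, operation, domain,
                    err.code))
            raise
        except BaseException:
            self._load_tree()
            raise

    # ------------------------------------------------------------------
    # domain operations

    def create_domain(self, name: str, spec: Optional[dict] = None,
                      parent: Optional[str] = None, privileged: bool = False,
                      actor: str = "anonymous",
                      actor_class: str = "human") -> DomainConfig:
        def work():
            cfg = self.tree.create(name, spec, parent, privileged)
            self.db.write_domain(self._domain_row(cfg))
            return cfg
        return self._audited("domain-create-privileged" if privileged
                             else "domain-create", "create", name, actor,
                             actor_class, work)

    def update_domain(self, name: str, changes: dict, propagate: bool = False,
                      privileged: bool = False, actor: str = "anonymous",
                      actor_class: str = "human") -> Dict[str, Set[str]]:
        """Apply changes; returns affected domain and record identifiers.

        The result maps each touched domain to its changed attributes, plus a
        ``"records"`` entry listing ``domain:pseudonym`` strings for records
        whose inherited validity bounds were propagated.
        """
        def work():
            affected = self.tree.update(name, changes, propagate, privileged)
            now = _iso(utcnow())
            touched_records: List[str] = []
            for dom, attrs in affected.items():
                self.db.write_domain(self._domain_row(self.tree.get(dom)))
                for attr in attrs & {"validity.start", "validity.end"}:
                    value = self.tree.get(dom).get_attribute(attr)
                    # the target domain's own overwritten records keep their
                    # values; only inherited flags track the domain
                    for pid in self.db.propagate_validity(dom, attr,
                                                          _iso(value), now):
                        touched_records.append(f"{dom}:{pid}")
            result = {dom: attrs for dom, attrs in affected.items()}
            result["records"] = set(touched_records)
            return result
        return self._audited("domain-update-privileged" if privileged
                             else "domain-update", "update", name, actor,
                             actor_class, work)

    def get_domain(self, name: str, actor: str = "anonymous",
                   actor_class: str = "human") -> DomainConfig:
        return self._audited("domain-read", "read", name, actor, actor_class,
                             lambda: self.tree.get(name))

    def get_domain_attribute(self, name: str, attribute: str,
                             privileged: bool = False,
                             actor: str = "anonymous",
                             actor_class: str = "human") -> Tuple[object, bool]:
        return self._audited(
            "domain-read", "read", name, actor, actor_class,
            lambda: self.tree.get_attribute(name, attribute, privileged))

    def set_domain_salt(self, name: str, salt: str, actor: str = "anonymous",
                        actor_class: str = "human") -> DomainConfig:
        def work():
            self.tree.get(name)
            if self.db.count_records(name):
                raise DomainNotEmptyError(
                    f"domain {name!r} already holds pseudonyms")
            cfg = self.tree.set_salt(name, salt)
            self.db.write_domain(self._domain_row(cfg))
            return cfg
        return self._audited("domain-salt", "update", name, actor,
                             actor_class, work)

    def delete_domain(self, name: str, actor: str = "anonymous",
                      actor_class: str = "human") -> bool:
        def work():
            self.tree.get(name)
            if self.db.count_records(name):
                raise DomainNotEmptyError(
                    f"domain {name!r} still holds pseudonyms")
            self.tree.delete(name)  # raises if child domains exist
            self.db.delete_domain_row(name)
            return True
        return self._audited("domain-delete", "delete", name, actor,
                             actor_class, work)

    def find_common_ancestor(self, d1: str, d2: str) -> Optional[str]:
        return self.tree.find_common_ancestor(d1, d2)

    # ------------------------------------------------------------------
    # pseudonym record operations

    def put_record(self, domain: str, identifier: str,
                   validity: Optional[ValidityPeriod] = None,
                   actor: str = "anonymous",
                   actor_class: str = "human") -> PseudonymRecord:
        """Create (or idempotently return) the pseudonym for an identifier."""
        def work():
            cfg = self.tree.get(domain)
            existing = self.db.fetch_record(domain, identifier=identifier)
            if existing is not None:
                return _record_from_row(existing)
            request = algorithms.GenerationRequest(
                identifier=identifier, config=cfg,
                uniqueness_check=lambda c: not self.db.pseudonym_exists(domain, c))
            pseudonym = algorithms.generate(request, self.rng)
            if cfg.algorithm == "consecutive":
                self.db.write_domain(self._domain_row(cfg))  # counter state
            now = _iso(utcnow())
            if validity is not None:
                v_start, v_end = validity.start, validity.end
                s_inh = e_inh = 0
            else:
                v_start, v_end = cfg.validity.start, cfg.validity.end
                s_inh = e_inh = 1
            row = {
                "domain": domain, "identifier": identifier,
                "pseudonym": pseudonym.full,
                "validity_start": _iso(v_start),
                "validity_start_inherited": s_inh,
                "validity_end": _iso(v_end),
                "validity_end_inherited": e_inh,
                "created_at": now, "updated_at": now,
            }
            self.db.insert_record(row)
            return _record_from_row(row)
        return self._audited("record-create", "create", domain, actor,
                             actor_class, work)

    # friendlier aliases
    def pseudonymize(self, domain: str, identifier: str, **kw) -> str:
        return self.put_record(domain, identifier, **kw).pseudonym

    def depseudonymize(self, domain: str, pseudonym: str, **kw) -> str:
        return self.resolve(domain, pseudonym,
                            direction="pseudonym->identifier", **kw).identifier

    def resolve(self, domain: str, key: str,
                direction: str = "identifier->pseudonym",
                at_time: Optional[datetime] = None,
                actor: str = "anonymous",
                actor_class: str = "human") -> PseudonymRecord:
        """Look a record up in either direction, honouring its validity period."""
        def work():
            self.tree.get(domain)
            if direction == "identifier->pseudonym":
                row = self.db.fetch_record(domain, identifier=key)
            elif direction == "pseudonym->identifier":
                row = self.db.fetch_record(domain, pseudonym=key)
            else:
                raise ValidationError(f"unknown direction {direction!r}")
            if row is None:
                raise NotFoundError(f"no record for {key!r} in {domain!r}")
            record = _record_from_row(row)
            at = at_time or utcnow()
            if not record.validity.contains(at):
                raise ExpiredError(
                    f"record for {key!r} not valid at {at.isoformat()}")
            return record
        return self._audited("record-read", "read", domain, actor,
                             actor_class, work)

    def update_record(self, domain: str, pseudonym: str, changes: dict,
                      privileged: bool = False, actor: str = "anonymous",
                      actor_class: str = "human") -> PseudonymRecord:
        """Standard updates touch only the validity period; the privileged
        variant may also rewrite the pseudonym string and the identifier."""
        def work():
            self.tree.get(domain)
            row = self.db.fetch_record(domain, pseudonym=pseudonym)
            if row is None:
                raise NotFoundError(f"no record {pseudonym!r} in {domain!r}")
            allowed = {"validity.start", "validity.end"}
            if not privileged and set(changes) - allowed:
                raise PrivilegeError(
                    "standard update may only change the validity period")
            unknown = set(changes) - allowed - {"pseudonym", "identifier"}
            if unknown:
                raise ValidationError(f"unknown changes {sorted(unknown)}")
            updates: dict = {"updated_at": _iso(utcnow())}
            if "validity.start" in changes:
                updates["validity_start"] = _iso(changes["validity.start"])
                updates["validity_start_inherited"] = 0
            if "validity.end" in changes:
                updates["validity_end"] = _iso(changes["validity.end"])
                updates["validity_end_inherited"] = 0
            if "pseudonym" in changes:
                new_p = changes["pseudonym"]
                if new_p != pseudonym and self.db.pseudonym_exists(domain, new_p):
                    raise UniquenessError(
                        f"pseudonym {new_p!r} already used in {domain!r}")
                updates["pseudonym"] = new_p
            if "identifier" in changes:
                other = self.db.fetch_record(domain,
                                             identifier=changes["identifier"])
                if other is not None and other["pseudonym"] != pseudonym:
                    raise UniquenessError(
                        f"identifier {changes['identifier']!r} already mapped")
                updates["identifier"] = changes["identifier"]
            self.db.update_record_row(domain, pseudonym, updates)
            return _record_from_row(
                self.db.fetch_record(domain,
                                     pseudonym=updates.get("pseudonym", pseudonym)))
        return self._audited("record-update-privileged" if privileged
                             else "record-update", "update", domain, actor,
                             actor_class, work)

    def delete_record(self, domain: str, pseudonym: str,
                      actor: str = "anonymous",
                      actor_class: str = "human") -> bool:
        def work():
            self.tree.get(domain)
            if not self.db.delete_record_row(domain, pseudonym):
                raise NotFoundError(f"no record {pseudonym!r} in {domain!r}")
            return True
        return self._audited("record-delete", "delete", domain, actor,
                             actor_class, work)

    def batch_ops(self, domain: str, operation: str, items: Sequence,
                  privileged: bool = False, actor: str = "anonymous",
                  actor_class: str = "technical") -> List[dict]:
        """Run one operation over many items in a single transaction.

        Per-item outcomes are reported individually (a failing item rolls
        back only its own savepoint) and each item is audited separately, so
        the per-pseudonym access history stays complete.
        """
        if not items:
            raise ValidationError("batch requires at least one item")
        dispatch = {
            "create": lambda item: self.put_record(
                domain, item, actor=actor, actor_class=actor_class).pseudonym,
            "read": lambda item: self.resolve(
                domain, item, direction="pseudonym->identifier", actor=actor,
                actor_class=actor_class).identifier,
            "update": lambda item: self.update_record(
                domain, item[0], item[1], privileged=privileged, actor=actor,
                actor_class=actor_class).pseudonym,
            "delete": lambda item: self.delete_record(
                domain, item, actor=actor, actor_class=actor_class),
        }
        if operation not in dispatch:
            raise ValidationError(f"unknown batch operation {operation!r}")
        results: List[dict] = []
        with self.db.transaction():
            for item in items:
                try:
                    value = dispatch[operation](item)
                    results.append({"item": item, "ok": True, "value": value})
                except PseudokitError as err:
                    results.append({"item": item, "ok": False,
                                    "error": err.code})
        return results

    # ------------------------------------------------------------------

    def purge_audit(self, now: Optional[datetime] = None,
                    actor: str = "system") -> int:
        return self.db.purge_audit(now, actor)


__all__ = ["Engine", "PseudonymRecord"]
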