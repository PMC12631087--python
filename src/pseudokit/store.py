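"""Transactional star-schema storage with an audit trail.

The schema mirrors the engine's data model: a central ``pseudonym`` fact
table referencing a ``domain`` dimension table (which self-references its
parent), and a free-standing ``audit_event`` table.  Attributes that take
part in inheritance carry a companion ``*_inherited`` flag column.

All mutations run inside explicit transactions; audit events are written in
the same transaction as the operation they record, so a rollback removes
both.  A single serialized connection guarded by a re-entrant lock makes the
store safe under concurrent threads; per-item savepoints let batch
operations report partial failures without aborting the whole batch.
"""

from __future__ import annotations

import sqlite3
import threading
from contextlib import contextmanager
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Dict, Iterator, List, Optional, Set, Tuple

from .errors import ValidationError

SCHEMA_DDL = """
CREATE TABLE IF NOT EXISTS domain (
    name                TEXT PRIMARY KEY,
    parent              TEXT REFERENCES domain(name),
    algorithm           TEXT NOT NULL,
    algorithm_inherited INTEGER NOT NULL DEFAULT 0,
    alphabet            TEXT NOT NULL,
    alphabet_inherited  INTEGER NOT NULL DEFAULT 0,
    length              INTEGER NOT NULL,
    length_inherited    INTEGER NOT NULL DEFAULT 0,
    length_explicit     INTEGER NOT NULL DEFAULT 0,
    padding_char        TEXT NOT NULL,
    padding_char_inherited INTEGER NOT NULL DEFAULT 0,
    prefix              TEXT NOT NULL DEFAULT '',
    prefix_inherited    INTEGER NOT NULL DEFAULT 0,
    check_digit         INTEGER NOT NULL,
    check_digit_inherited INTEGER NOT NULL DEFAULT 0,
    check_digit_explicit INTEGER NOT NULL DEFAULT 0,
    salt                TEXT NOT NULL,
    retries             INTEGER NOT NULL,
    retries_inherited   INTEGER NOT NULL DEFAULT 0,
    capacity_target     INTEGER NOT NULL,
    capacity_target_inherited INTEGER NOT NULL DEFAULT 0,
    success_threshold   REAL NOT NULL,
    success_threshold_inherited INTEGER NOT NULL DEFAULT 0,
    validity_start      TEXT,
    validity_start_inherited INTEGER NOT NULL DEFAULT 0,
    validity_end        TEXT,
    validity_end_inherited INTEGER NOT NULL DEFAULT 0,
    counter_state       INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE IF NOT EXISTS pseudonym (
    domain              TEXT NOT NULL REFERENCES domain(name),
    identifier          TEXT NOT NULL,
    pseudonym           TEXT NOT NULL,
    validity_start      TEXT,
    validity_start_inherited INTEGER NOT NULL DEFAULT 1,
    validity_end        TEXT,
    validity_end_inherited INTEGER NOT NULL DEFAULT 1,
    created_at          TEXT NOT NULL,
    updated_at          TEXT NOT NULL,
    PRIMARY KEY (domain, identifier),
    UNIQUE (domain, pseudonym)
);

CREATE TABLE IF NOT EXISTS audit_event (
    id          INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp   TEXT NOT NULL,
    actor       TEXT NOT NULL,
    actor_class TEXT NOT NULL,
    action      TEXT NOT NULL,
    operation   TEXT NOT NULL,
    domain      TEXT,
    outcome     TEXT NOT NULL
);
"""


def utcnow() -> datetime:
    return datetime.now(timezone.utc)


def _iso(ts: Optional[datetime]) -> Optional[str]:
    return ts.isoformat() if ts is not None else None


def _from_iso(value: Optional[str]) -> Optional[datetime]:
    return datetime.fromisoformat(value) if value else None


@dataclass(frozen=True)
class AuditEvent:
    """One immutable access record, written atomically with its operation."""

    timestamp: datetime
    actor: str
    actor_class: str
    action: str  # create | read | update | delete
    operation: str
    domain: Optional[str]
    outcome: str  # "success" or an error code


@dataclass
class AuditPolicy:
    """Selects which (action, actor class) pairs are recorded per operation.

    ``operations`` maps an operation name to the set of (action, actor_class)
    combinations to record; operations absent from the map record everything.
    ``retention_period`` bounds how long events are kept.
    """

    operations: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    retention_period: timedelta = timedelta(days=3650)

    def __post_init__(self):
        if self.retention_period <= timedelta(0):
            raise ValidationError("retention period must be strictly positive")

    def should_record(self, operation: str, action: str, actor_class: str) -> bool:
        if operation not in self.operations:
            return True
        return (action, actor_class) in self.operations[operation]


class Database:
    """Embedded SQL storage (single sqlite file, or in-memory by default)."""

    def __init__(self, path: str = ":memory:",
                 policy: Optional[AuditPolicy] = None):
        self._conn = sqlite3.connect(path, check_same_thread=False,
                                     isolation_level=None)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(SCHEMA_DDL)
        self._lock = threading.RLock()
        self._tx_depth = 0
        self.policy = policy or AuditPolicy()

    # -- transactions -----------------------------------------------------

    @contextmanager
    def transaction(self) -> Iterator[sqlite3.Connection]:
        """All writes inside the block commit together or not at all.

        Nested use creates a savepoint, so an inner failure rolls back only
        the inner work (used by batch operations for per-item isolation).
        """
        with self._lock:
            if self._tx_depth == 0:
                self._conn.execute("BEGIN IMMEDIATE")
            else:
                self._conn.execute(f"SAVEPOINT sp{self._tx_depth}")
            self._tx_depth += 1
            try:
                yield self._conn
            except BaseException:
                self._tx_depth -= 1
                if self._tx_depth == 0:
                    self._conn.execute("ROLLBACK")
                else:
                    self._conn.execute(f"ROLLBACK TO sp{self._tx_depth}")
                    self._conn.execute(f"RELEASE sp{self._tx_depth}")
                raise
            else:
                self._tx_depth -= 1
                if self._tx_depth == 0:
                    self._conn.execute("COMMIT")
                else:
                    self._conn.execute(f"RELEASE sp{self._tx_depth}")

    def with_transaction(self, work):
        """Run ``work()`` transactionally and return its result."""
        with self.transaction():
            return work()

    # -- audit ------------------------------------------------------------

    def record_audit(self, event: AuditEvent) -> bool:
        """Write one audit event (inside the caller's transaction).

        Returns False when the policy filters the event out.
        """
        if not self.policy.should_record(event.operation, event.action,
                                         event.actor_class):
            return False
        self._conn.execute(
            "INSERT INTO audit_event (timestamp, actor, actor_class, action,"
            " operation, domain, outcome) VALUES (?, ?, ?, ?, ?, ?, ?)",
            (_iso(event.timestamp), event.actor, event.actor_class,
             event.action, event.operation, event.domain, event.outcome))
        return True

    def audit_events(self, domain: Optional[str] = None) -> List[AuditEvent]:
        with self._lock:
            sql = ("SELECT timestamp, actor, actor_class, action, operation,"
                   " domain, outcome FROM audit_event")
            args: tuple = ()
            if domain is not None:
                sql += " WHERE domain = ?"
                args = (domain,)
            rows = self._conn.execute(sql + " ORDER BY id", args).fetchall()
        return [AuditEvent(_from_iso(r[0]), r[1], r[2], r[3], r[4], r[5], r[6])
                for r in rows]

    def purge_audit(self, now: Optional[datetime] = None,
                    actor: str = "system") -> int:
        """Remove events older than the retention period; log the purge."""
        now = now or utcnow()
        cutoff = now - self.policy.retention_period
        with self.transaction():
            cur = self._conn.execute(
                "DELETE FROM audit_event WHERE timestamp < ?", (_iso(cutoff),))
            purged = cur.rowcount
            self.record_audit(AuditEvent(now, actor, "technical", "delete",
                                         "audit-purge", None,
                                         f"purged:{purged}"))
        return purged

    def export_audit(self) -> List[dict]:
        """Audit trail as newline-serialisable records."""
        return [
            {"timestamp": _iso(e.timestamp), "actor": e.actor,
             "actor_class": e.actor_class, "action": e.action,
             "operation": e.operation, "domain": e.domain,
             "outcome": e.outcome}
            for e in self.audit_events()
        ]

    # -- domain rows -------------------------------------------------------

    def write_domain(self, doc: dict) -> None:
        cols = list(doc)
        self._conn.execute(
            f"INSERT OR REPLACE INTO domain ({', '.join(cols)})"
            f" VALUES ({', '.join('?' * len(cols))})",
            [doc[c] for c in cols])

    def delete_domain_row(self, name: str) -> None:
        self._conn.execute("DELETE FROM domain WHERE name = ?", (name,))

    def load_domain_rows(self) -> List[dict]:
        with self._lock:
            cur = self._conn.execute("SELECT * FROM domain")
            names = [d[0] for d in cur.description]
            return [dict(zip(names, row)) for row in cur.fetchall()]

    # -- pseudonym rows ----------------------------------------------------

    def insert_record(self, row: dict) -> None:
        cols = list(row)
        self._conn.execute(
            f"INSERT INTO pseudonym ({', '.join(cols)})"
            f" VALUES ({', '.join('?' * len(cols))})",
            [row[c] for c in cols])

    def fetch_record(self, domain: str, *, identifier: Optional[str] = None,
                     pseudonym: Optional[str] = None) -> Optional[dict]:
        key, value = (("identifier", identifier) if identifier is not None
                      else ("pseudonym", pseudonym))
        with self._lock:
            cur = self._conn.execute(
                f"SELECT * FROM pseudonym WHERE domain = ? AND {key} = ?",
                (domain, value))
            names = [d[0] for d in cur.description]
            row = cur.fetchone()
        return dict(zip(names, row)) if row else None

    def records_in_domains(self, domains: List[str]) -> List[dict]:
        if not domains:
            return []
        with self._lock:
            marks = ", ".join("?" * len(domains))
            cur = self._conn.execute(
                f"SELECT * FROM pseudonym WHERE domain IN ({marks})", domains)
            names = [d[0] for d in cur.description]
            return [dict(zip(names, row)) for row in cur.fetchall()]

    def count_records(self, domain: str) -> int:
        with self._lock:
            return self._conn.execute(
                "SELECT COUNT(*) FROM pseudonym WHERE domain = ?",
                (domain,)).fetchone()[0]

    def pseudonym_exists(self, domain: str, pseudonym: str) -> bool:
        with self._lock:
            return self._conn.execute(
                "SELECT 1 FROM pseudonym WHERE domain = ? AND pseudonym = ?",
                (domain, pseudonym)).fetchone() is not None

    def update_record_row(self, domain: str, pseudonym: str,
                          updates: dict) -> int:
        sets = ", ".join(f"{c} = ?" for c in updates)
        cur = self._conn.execute(
            f"UPDATE pseudonym SET {sets} WHERE domain = ? AND pseudonym = ?",
            [*updates.values(), domain, pseudonym])
        return cur.rowcount

    def propagate_validity(self, domain: str, attr: str, value: Optional[str],
                           now: str) -> List[str]:
        """Push an inherited validity bound into this domain's records.

        Only records whose flag for the bound is still *inherited* change;
        returns the affected pseudonym strings.
        """
        col = "validity_start" if attr == "validity.start" else "validity_end"
        with self._lock:
            rows = self._conn.execute(
                f"SELECT pseudonym FROM pseudonym WHERE domain = ?"
                f" AND {col}_inherited = 1", (domain,)).fetchall()
            self._conn.execute(
                f"UPDATE pseudonym SET {col} = ?, updated_at = ?"
                f" WHERE domain = ? AND {col}_inherited = 1",
                (value, now, domain))
        return [r[0] for r in rows]

    def delete_record_row(self, domain: str, pseudonym: str) -> int:
        cur = self._conn.execute(
            "DELETE FROM pseudonym WHERE domain = ? AND pseudonym = ?",
            (domain, pseudonym))
        return cur.rowcount

    def snapshot(self) -> Tuple[tuple, ...]:
        """Bit-level view of all three tables, for rollback assertions."""
        with self._lock:
            out = []
            for table in ("domain", "pseudonym", "audit_event"):
                out.append(tuple(self._conn.execute(
                    f"SELECT * FROM {table}").fetchall()))
            return tuple(out)

    def close(self) -> None:
        self._conn.close()


__all__ = ["Database", "AuditEvent", "AuditPolicy", "SCHEMA_DDL", "utcnow"]
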