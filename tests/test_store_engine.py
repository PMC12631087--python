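"""Transactional storage, audit trail, and engine record semantics."""

import random
import threading
from datetime import datetime, timedelta, timezone

import pytest

from pseudokit import Engine, ValidityPeriod
from pseudokit.errors import (
    DomainNotEmptyError,
    ExhaustedRetriesError,
    ExpiredError,
    NotFoundError,
    PrivilegeError,
    UniquenessError,
    ValidationError,
)
from pseudokit.store import AuditEvent, AuditPolicy, Database, utcnow


def _t(day, hour=0):
    return datetime(2024, 3, day, hour, tzinfo=timezone.utc)


# ---------------------------------------------------------------------------
# Transactions and audit atomicity

def test_rollback_leaves_tables_bit_identical(engine):
    engine.create_domain("d")
    engine.put_record("d", "alice")
    before = engine.db.snapshot()
    with pytest.raises(RuntimeError):
        with engine.db.transaction():
            engine.db.insert_record({
                "domain": "d", "identifier": "bob", "pseudonym": "XYZ",
                "validity_start": None, "validity_start_inherited": 1,
                "validity_end": None, "validity_end_inherited": 1,
                "created_at": "x", "updated_at": "x"})
            engine.db.record_audit(AuditEvent(
                utcnow(), "t", "human", "create", "record-create", "d", "success"))
            raise RuntimeError("injected mid-transaction failure")
    assert engine.db.snapshot() == before


def test_successful_create_writes_one_record_and_one_audit_event(engine):
    engine.create_domain("d")
    baseline = len(engine.db.audit_events())
    engine.put_record("d", "alice")
    assert engine.db.count_records("d") == 1
    events = engine.db.audit_events()
    assert len(events) == baseline + 1
    last = events[-1]
    assert (last.action, last.operation, last.domain, last.outcome) == \
        ("create", "record-create", "d", "success")


def test_failed_lookup_is_audited_with_error_outcome(engine):
    engine.create_domain("d")
    baseline = len(engine.db.audit_events())
    with pytest.raises(NotFoundError):
        engine.resolve("d", "ghost")
    last = engine.db.audit_events()[-1]
    assert last.outcome == "not-found" and last.action == "read"
    assert len(engine.db.audit_events()) == baseline + 1


def test_audit_policy_filters_events():
    policy = AuditPolicy(operations={"record-read": {("read", "human")}})
    eng = Engine(Database(policy=policy), rng=random.Random(0))
    eng.create_domain("d")
    eng.put_record("d", "a")  # record-create not in map: recorded
    n0 = len(eng.db.audit_events())
    with pytest.raises(NotFoundError):
        eng.resolve("d", "nope", actor_class="technical")  # filtered
    assert len(eng.db.audit_events()) == n0
    with pytest.raises(NotFoundError):
        eng.resolve("d", "nope", actor_class="human")  # recorded
    assert len(eng.db.audit_events()) == n0 + 1


def test_purge_audit_removes_only_over_age_events(engine):
    engine.db.policy = AuditPolicy(retention_period=timedelta(days=1))
    engine.create_domain("d")
    # backdate half the events by two days
    engine.db._conn.execute(
        "UPDATE audit_event SET timestamp = ? WHERE id % 2 = 0",
        ((utcnow() - timedelta(days=2)).isoformat(),))
    total = len(engine.db.audit_events())
    over_age = total // 2
    purged = engine.purge_audit()
    assert purged == over_age
    # the purge itself is logged
    assert engine.db.audit_events()[-1].operation == "audit-purge"


def test_retention_period_must_be_positive():
    with pytest.raises(ValidationError):
        AuditPolicy(retention_period=timedelta(0))


# ---------------------------------------------------------------------------
# Record CRUD

def test_put_record_is_idempotent(engine):
    engine.create_domain("d")
    first = engine.put_record("d", "alice")
    second = engine.put_record("d", "alice")
    assert first.pseudonym == second.pseudonym
    assert engine.db.count_records("d") == 1


def test_distinct_identifiers_get_distinct_pseudonyms(engine):
    engine.create_domain("d")
    pseudonyms = {engine.put_record("d", f"id{i}").pseudonym for i in range(50)}
    assert len(pseudonyms) == 50


def test_full_single_digit_namespace_exhausts_retries(engine):
    engine.create_domain(
        "tiny", {"algorithm": "random_string", "alphabet": "digits",
                 "length": 1, "check_digit": False, "retries": 200},
        privileged=True)
    for i in range(10):
        engine.put_record("tiny", f"id{i}")
    assert engine.db.count_records("tiny") == 10
    with pytest.raises(ExhaustedRetriesError):
        engine.put_record("tiny", "one-too-many")


def test_resolve_round_trip_and_both_directions(engine):
    engine.create_domain("d")
    pseudonym = engine.pseudonymize("d", "alice")
    assert engine.depseudonymize("d", pseudonym) == "alice"
    rec = engine.resolve("d", "alice", direction="identifier->pseudonym")
    assert rec.pseudonym == pseudonym


def test_resolve_outside_validity_period_is_expired(engine):
    engine.create_domain("d", {"validity.start": _t(1), "validity.end": _t(10)})
    p = engine.pseudonymize("d", "alice")
    assert engine.resolve("d", p, direction="pseudonym->identifier",
                          at_time=_t(5)).identifier == "alice"
    with pytest.raises(ExpiredError):
        engine.resolve("d", p, direction="pseudonym->identifier",
                       at_time=_t(10))  # half-open [start, end)
    with pytest.raises(ExpiredError):
        engine.resolve("d", p, direction="pseudonym->identifier",
                       at_time=_t(12))


def test_standard_update_restricted_to_validity(engine):
    engine.create_domain("d")
    p = engine.pseudonymize("d", "alice")
    rec = engine.update_record("d", p, {"validity.end": _t(20)})
    assert rec.validity.end == _t(20)
    assert rec.validity_end_inherited is False
    with pytest.raises(PrivilegeError):
        engine.update_record("d", p, {"pseudonym": "NEW"})


def test_privileged_update_changes_pseudonym_with_uniqueness_check(engine):
    engine.create_domain("d")
    p1 = engine.pseudonymize("d", "alice")
    p2 = engine.pseudonymize("d", "bob")
    with pytest.raises(UniquenessError):
        engine.update_record("d", p1, {"pseudonym": p2}, privileged=True)
    rec = engine.update_record("d", p1, {"pseudonym": "CUSTOM1"},
                               privileged=True)
    assert rec.pseudonym == "CUSTOM1"
    assert engine.depseudonymize("d", "CUSTOM1") == "alice"


def test_delete_then_resolve_not_found(engine):
    engine.create_domain("d")
    p = engine.pseudonymize("d", "alice")
    engine.delete_record("d", p)
    with pytest.raises(NotFoundError):
        engine.resolve("d", p, direction="pseudonym->identifier")


def test_set_salt_only_on_empty_domain(engine):
    engine.create_domain("d")
    engine.set_domain_salt("d", "fresh-salt")
    engine.pseudonymize("d", "alice")
    with pytest.raises(DomainNotEmptyError):
        engine.set_domain_salt("d", "another")


def test_delete_domain_requires_no_records(engine):
    engine.create_domain("d")
    engine.pseudonymize("d", "alice")
    with pytest.raises(DomainNotEmptyError):
        engine.delete_domain("d")


# ---------------------------------------------------------------------------
# Batch operations

def test_batch_create_counts_records_and_audit_events(engine):
    engine.create_domain("d")
    baseline = len(engine.db.audit_events())
    results = engine.batch_ops("d", "create", [f"id{i}" for i in range(100)])
    assert all(r["ok"] for r in results)
    assert engine.db.count_records("d") == 100
    # one audit event per item, not one per batch
    assert len(engine.db.audit_events()) == baseline + 100


def test_batch_read_reports_per_item_failures(engine):
    engine.create_domain("d")
    keys = [engine.pseudonymize("d", f"id{i}") for i in range(9)]
    results = engine.batch_ops("d", "read", keys + ["UNKNOWN"])
    assert sum(r["ok"] for r in results) == 9
    assert results[-1] == {"item": "UNKNOWN", "ok": False, "error": "not-found"}


def test_batch_requires_at_least_one_item(engine):
    engine.create_domain("d")
    with pytest.raises(ValidationError):
        engine.batch_ops("d", "create", [])


# ---------------------------------------------------------------------------
# Concurrency

def test_concurrent_same_identifier_creates_exactly_one_record(engine):
    engine.create_domain("d")
    outcomes = []

    def create():
        outcomes.append(engine.put_record("d", "shared").pseudonym)

    threads = [threading.Thread(target=create) for _ in range(8)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    assert len(set(outcomes)) == 1
    assert engine.db.count_records("d") == 1


def test_concurrent_batches_preserve_uniqueness_invariants(engine):
    engine.create_domain("d")

    def batch(offset):
        engine.batch_ops("d", "create",
                         [f"w{offset}-{i}" for i in range(40)])

    threads = [threading.Thread(target=batch, args=(w,)) for w in range(4)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    rows = engine.db.records_in_domains(["d"])
    assert len(rows) == 160
    assert len({r["pseudonym"] for r in rows}) == 160
    assert len({r["identifier"] for r in rows}) == 160


# ---------------------------------------------------------------------------
# Persistence across engine instances (domains reload from rows)

def test_engine_reloads_domain_tree_from_database(tmp_path):
    path = str(tmp_path / "store.db")
    eng1 = Engine(Database(path), rng=random.Random(0))
    eng1.create_domain("p", {"algorithm": "sha2"})
    eng1.create_domain("c", parent="p")
    p = eng1.pseudonymize("c", "alice")
    eng1.db.close()

    eng2 = Engine(Database(path), rng=random.Random(0))
    assert eng2.get_domain_attribute("c", "algorithm") == ("sha2", True)
    assert eng2.depseudonymize("c", p) == "alice"
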