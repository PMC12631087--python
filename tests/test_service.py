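"""Endpoint surface, group-path authorization, linked-pseudonym traversal."""

import random

import pytest

from pseudokit import Engine, Principal, Request, Service, authorize
from pseudokit.errors import NotFoundError, UnauthorizedError
from pseudokit.service import ACTION_CLASSES, ENDPOINTS, StaticTokenAuthenticator
from pseudokit.store import Database


@pytest.fixture
def service(engine):
    return Service(engine)


def _principal(*paths, user="foo"):
    return Principal(user, frozenset(paths))


ADMIN = Principal("admin", frozenset(
    f"/{ac}/{dom}" for ac in ACTION_CLASSES
    for dom in ("d", "p", "c1", "c2", "g", "x", "y")))


# ---------------------------------------------------------------------------
# Authorization

def test_authorize_requires_exact_group_path():
    principal = _principal("/record-read/bar")
    assert authorize(principal, "record-read", "bar")
    assert not authorize(principal, "record-read", "baz")
    assert not authorize(principal, "record-delete", "bar")
    assert not authorize(None, "record-read", "bar")


def test_rights_do_not_inherit_down_the_domain_tree(service):
    service.engine.create_domain("p", actor="setup")
    service.engine.create_domain("c1", parent="p", actor="setup")
    principal = _principal("/record-create/p")
    ok = service.handle(Request("POST", "/domains/p/pseudonym",
                                {"identifier": "a"}), principal)
    assert ok.status == 201
    denied = service.handle(Request("POST", "/domains/c1/pseudonym",
                                    {"identifier": "a"}), principal)
    assert denied.status == 403


def test_authorization_fuzz_allow_iff_exact_path_present(service):
    """Randomized (principal, endpoint, domain) triples: allow exactly when
    the matching group path is held."""
    service.engine.create_domain("d", actor="setup")
    service.engine.pseudonymize("d", "alice", actor="setup")
    rng = random.Random(42)
    probes = [
        ("GET", "/domains/{dom}/pseudonym", "record-read", {"key": "alice"}),
        ("POST", "/domains/{dom}/pseudonym", "record-create",
         {"identifier": "alice"}),
        ("DELETE", "/domains/{dom}/pseudonym", "record-delete",
         {"pseudonym": "nope"}),
        ("GET", "/domains/{dom}/algorithm", "domain-read", {}),
        ("PUT", "/domains/{dom}/salt", "domain-salt", {"salt": "s"}),
    ]
    for _ in range(60):
        method, template, action, params = rng.choice(probes)
        dom = rng.choice(["d", "other"])
        held = {f"/{rng.choice(list(ACTION_CLASSES))}/{rng.choice(['d', 'other'])}"
                for _ in range(rng.randint(0, 3))}
        expect_allow = f"/{action}/{dom}" in held
        resp = service.handle(
            Request(method, template.format(dom=dom), dict(params)),
            Principal("fuzz", frozenset(held)))
        if expect_allow:
            assert resp.status != 403, (method, template, dom, held)
        else:
            assert resp.status == 403


def test_unauthenticated_request_rejected_except_ping(service):
    assert service.handle(Request("GET", "/ping")).status == 200
    resp = service.handle(Request("GET", "/domains/d/pseudonym", {"key": "x"}))
    assert resp.status == 401


def test_static_token_authenticator_contract():
    principal = _principal("/record-read/d")
    auth = StaticTokenAuthenticator({"secret": principal})
    assert auth("secret") is principal
    assert auth("wrong") is None
    assert auth(None) is None


# ---------------------------------------------------------------------------
# Dispatch and content negotiation

def test_ping_touches_no_storage(service):
    before = service.engine.db.snapshot()
    resp = service.handle(Request("GET", "/ping"))
    assert resp.status == 200
    assert service.engine.db.snapshot() == before


def test_plain_text_negotiation_returns_bare_pseudonym(service):
    service.engine.create_domain("d", actor="setup")
    p = service.engine.pseudonymize("d", "alice", actor="setup")
    resp = service.handle(
        Request("GET", "/domains/d/pseudonym", {"key": "alice"},
                accept="text"), ADMIN)
    assert resp.content_type == "text/plain"
    assert resp.body == p
    json_resp = service.handle(
        Request("GET", "/domains/d/pseudonym", {"key": "alice"}), ADMIN)
    assert json_resp.body == {"identifier": "alice", "pseudonym": p}


def test_read_negotiation_never_changes_state(service):
    service.engine.create_domain("d", actor="setup")
    service.engine.pseudonymize("d", "alice", actor="setup")
    before = service.engine.db.records_in_domains(["d"])
    for accept in ("json", "text", "json"):
        service.handle(Request("GET", "/domains/d/pseudonym",
                               {"key": "alice"}, accept=accept), ADMIN)
    assert service.engine.db.records_in_domains(["d"]) == before


def test_domain_crud_and_attribute_endpoint(service):
    resp = service.handle(Request("POST", "/domain",
                                  {"name": "d", "spec": {"algorithm": "sha1"}}),
                          ADMIN)
    assert resp.status == 201
    attr = service.handle(Request("GET", "/domains/d/algorithm"), ADMIN)
    assert attr.body == {"attribute": "algorithm", "value": "sha1",
                         "inherited": False}
    resp = service.handle(Request("DELETE", "/domain", {"name": "d"}), ADMIN)
    assert resp.status == 200


def test_error_statuses_are_distinguishable(service):
    service.engine.create_domain("d", actor="setup")
    assert service.handle(Request("GET", "/domains/d/pseudonym",
                                  {"key": "ghost"}), ADMIN).status == 404
    assert service.handle(Request("POST", "/domain", {"name": "d"}),
                          ADMIN).status == 409
    assert service.handle(Request("GET", "/nonsense", {}), ADMIN).status == 404


def test_every_table_endpoint_is_described():
    surface = {(ep.path, ep.method) for ep in ENDPOINTS}
    for path, methods in [
        ("/domain", ("POST", "GET", "PUT", "DELETE")),
        ("/domain/privileged", ("POST", "PUT")),
        ("/domains/{domain}/{attribute}", ("GET",)),
        ("/domains/{domain}/salt", ("PUT",)),
        ("/domains/{domain}/pseudonym", ("POST", "GET", "PUT", "DELETE")),
        ("/domains/{domain}/pseudonym/privileged", ("PUT",)),
        ("/domains/{domain}/pseudonyms", ("POST", "GET", "PUT", "DELETE")),
        ("/domains/linked-pseudonyms", ("GET",)),
        ("/ping", ("GET",)),
    ]:
        for method in methods:
            assert (path, method) in surface


def test_batch_endpoint_runs_in_one_call(service):
    service.engine.create_domain("d", actor="setup")
    resp = service.handle(
        Request("POST", "/domains/d/pseudonyms",
                {"items": ["a", "b", "c"]}), ADMIN)
    assert resp.status == 200
    assert [r["ok"] for r in resp.body["results"]] == [True] * 3


# ---------------------------------------------------------------------------
# Linked pseudonyms

@pytest.fixture
def linked_setup():
    eng = Engine(Database(), rng=random.Random(8))
    svc = Service(eng)
    eng.create_domain("p", actor="setup")
    eng.create_domain("x", parent="p", actor="setup")
    eng.create_domain("y", parent="p", actor="setup")
    eng.create_domain("island", actor="setup")
    return eng, svc


def test_shared_identifier_links_sibling_domains(linked_setup):
    eng, svc = linked_setup
    px = eng.pseudonymize("x", "alice", actor="setup")
    py = eng.pseudonymize("y", "alice", actor="setup")
    principal = _principal("/record-read/x", "/record-read/y")
    assert svc.linked_pseudonyms(px, "x", "y", principal) == [py]


def test_pseudonym_chain_parent_to_child(linked_setup):
    eng, svc = linked_setup
    pp = eng.pseudonymize("p", "alice", actor="setup")
    # the child record's identifier is the parent's pseudonym
    px = eng.pseudonymize("x", pp, actor="setup")
    principal = _principal("/record-read/p", "/record-read/x")
    assert svc.linked_pseudonyms(pp, "p", "x", principal) == [px]
    # symmetric: query from the child back to the parent
    assert svc.linked_pseudonyms(px, "x", "p", principal) == [pp]


def test_disjoint_trees_yield_not_found(linked_setup):
    eng, svc = linked_setup
    eng.pseudonymize("island", "alice", actor="setup")
    px = eng.pseudonymize("x", "alice", actor="setup")
    principal = _principal("/record-read/x", "/record-read/island")
    with pytest.raises(NotFoundError) as excinfo:
        svc.linked_pseudonyms(px, "x", "island", principal)
    assert excinfo.value.context["reason"] == "no-common-ancestor"


def test_unknown_source_pseudonym_distinguished(linked_setup):
    eng, svc = linked_setup
    principal = _principal("/record-read/x", "/record-read/y")
    with pytest.raises(NotFoundError) as excinfo:
        svc.linked_pseudonyms("NOPE", "x", "y", principal)
    assert excinfo.value.context["reason"] == "unknown-source-pseudonym"


def test_linked_requires_read_rights_on_both_domains(linked_setup):
    eng, svc = linked_setup
    px = eng.pseudonymize("x", "alice", actor="setup")
    with pytest.raises(UnauthorizedError):
        svc.linked_pseudonyms(px, "x", "y", _principal("/record-read/x"))


def test_link_closure_is_transitive_across_chains(linked_setup):
    """alice's record in x, chained into y via p: closure crosses both edges."""
    eng, svc = linked_setup
    pp = eng.pseudonymize("p", "alice", actor="setup")
    px = eng.pseudonymize("x", "alice", actor="setup")   # shared identifier
    py = eng.pseudonymize("y", pp, actor="setup")        # chain p -> y
    principal = _principal("/record-read/x", "/record-read/y",
                           "/record-read/p")
    assert svc.linked_pseudonyms(px, "x", "y", principal) == [py]
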