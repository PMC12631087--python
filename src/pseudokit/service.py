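"""REST-style operation surface: endpoints, authorization, linked pseudonyms.

The service is an in-process request dispatcher exposing the exact endpoint
templates of the engine's HTTP surface (``/domain``, ``/domains/{domain}/
pseudonym``, batch and privileged variants, ``/domains/linked-pseudonyms``,
``/ping``).  Authentication is a pluggable contract: anything that can turn a
token into a :class:`Principal` (user id plus a set of group paths such as
``/record-read/bar``) can back it; a static token map serves in tests.
Authorization is exact-match on ``/<action-class>/<domain>`` — rights do not
inherit down the domain tree, which is stricter than granting by subtree and
therefore the safe default.

Responses are structured dictionaries by default; plain text can be requested
per call (content negotiation), which never changes stored state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Dict, List, Optional, Tuple

from .domains import ValidityPeriod
from .engine import Engine
from .errors import (
    DomainNotEmptyError,
    DuplicateNameError,
    ExpiredError,
    NotFoundError,
    PrivilegeError,
    PseudokitError,
    UnauthorizedError,
    UniquenessError,
    ExhaustedRetriesError,
    HashCollisionError,
    ValidationError,
)

#: Fixed vocabulary of action classes appearing in group paths.
ACTION_CLASSES = (
    "record-create", "record-read", "record-update", "record-delete",
    "record-update-privileged",
    "domain-create", "domain-read", "domain-update", "domain-delete",
    "domain-create-privileged", "domain-update-privileged", "domain-salt",
)


@dataclass(frozen=True)
class Principal:
    """An authenticated caller: user id plus exact-match group paths."""

    user: str
    group_paths: frozenset = frozenset()
    actor_class: str = "human"


def authorize(principal: Optional[Principal], action_class: str,
              domain: str) -> bool:
    """Allow iff the principal holds the exact "/<action-class>/<domain>" path."""
    if principal is None:
        return False
    return f"/{action_class}/{domain}" in principal.group_paths


class StaticTokenAuthenticator:
    """Test/deployment stub for the pluggable token -> Principal contract."""

    def __init__(self, tokens: Dict[str, Principal]):
        self._tokens = dict(tokens)

    def __call__(self, token: Optional[str]) -> Optional[Principal]:
        return self._tokens.get(token) if token else None


@dataclass(frozen=True)
class EndpointDescriptor:
    """One route: path template, HTTP method, required action class."""

    path: str
    method: str
    action_class: Optional[str]  # None: unauthenticated (ping)
    privileged: bool = False


ENDPOINTS: Tuple[EndpointDescriptor, ...] = (
    EndpointDescriptor("/ping", "GET", None),
    EndpointDescriptor("/domain", "POST", "domain-create"),
    EndpointDescriptor("/domain", "GET", "domain-read"),
    EndpointDescriptor("/domain", "PUT", "domain-update"),
    EndpointDescriptor("/domain", "DELETE", "domain-delete"),
    EndpointDescriptor("/domain/privileged", "POST",
                       "domain-create-privileged", privileged=True),
    EndpointDescriptor("/domain/privileged", "PUT",
                       "domain-update-privileged", privileged=True),
    EndpointDescriptor("/domains/{domain}/salt", "PUT", "domain-salt"),
    EndpointDescriptor("/domains/{domain}/pseudonym", "POST", "record-create"),
    EndpointDescriptor("/domains/{domain}/pseudonym", "GET", "record-read"),
    EndpointDescriptor("/domains/{domain}/pseudonym", "PUT", "record-update"),
    EndpointDescriptor("/domains/{domain}/pseudonym", "DELETE", "record-delete"),
    EndpointDescriptor("/domains/{domain}/pseudonym/privileged", "PUT",
                       "record-update-privileged", privileged=True),
    EndpointDescriptor("/domains/{domain}/pseudonyms", "POST", "record-create"),
    EndpointDescriptor("/domains/{domain}/pseudonyms", "GET", "record-read"),
    EndpointDescriptor("/domains/{domain}/pseudonyms", "PUT", "record-update"),
    EndpointDescriptor("/domains/{domain}/pseudonyms", "DELETE", "record-delete"),
    EndpointDescriptor("/domains/linked-pseudonyms", "GET", "record-read"),
    EndpointDescriptor("/domains/{domain}/{attribute}", "GET", "domain-read"),
)

_STATUS = {
    ValidationError: 400,
    PrivilegeError: 403,
    NotFoundError: 404,
    ExpiredError: 410,
    DuplicateNameError: 409,
    UniquenessError: 409,
    DomainNotEmptyError: 409,
    ExhaustedRetriesError: 409,
    HashCollisionError: 409,
}


def _status_for(err: PseudokitError) -> int:
    for cls, status in _STATUS.items():
        if isinstance(err, cls):
            return status
    return 400


@dataclass(frozen=True)
class Request:
    """An endpoint invocation (the in-process analogue of an HTTP request)."""

    method: str
    path: str
    params: dict = field(default_factory=dict)
    accept: str = "json"  # "json" (default) or "text"


@dataclass(frozen=True)
class Response:
    status: int
    body: object
    content_type: str = "application/json"

    @property
    def ok(self) -> bool:
        return self.status < 400


def _match(template: str, path: str) -> Optional[dict]:
    t_parts = template.strip("/").split("/")
    p_parts = path.strip("/").split("/")
    if len(t_parts) != len(p_parts):
        return None
    params = {}
    for t, p in zip(t_parts, p_parts):
        if t.startswith("{") and t.endswith("}"):
            params[t[1:-1]] = p
        elif t != p:
            return None
    return params


class Service:
    """Dispatches requests to the engine after authorization."""

    def __init__(self, engine: Engine):
        self.engine = engine

    # -- linked pseudonyms ----------------------------------------------

    def linked_pseudonyms(self, source_pseudonym: str, source_domain: str,
                          target_domain: str,
                          principal: Principal) -> List[str]:
        """All pseudonyms in the target domain linked to the source pseudonym.

        Records are *linked* when they share an identifier inside the common-
        ancestor subtree, or when one record's identifier is another record's
        pseudonym along a parent-to-child chain (pseudonym chaining).  The
        link relation is closed symmetrically and transitively.  Without a
        common ancestor the lookup is a not-found.
        """
        for dom in (source_domain, target_domain):
            if not authorize(principal, "record-read", dom):
                raise UnauthorizedError(f"record-read on {dom!r} denied")
        ancestor = self.engine.find_common_ancestor(source_domain, target_domain)
        if ancestor is None:
            raise NotFoundError("domains share no common ancestor",
                                reason="no-common-ancestor")
        subtree = self.engine.tree.subtree(ancestor)
        rows = self.engine.db.records_in_domains(subtree)
        key = {(r["domain"], r["pseudonym"]): i for i, r in enumerate(rows)}

        parent = {i: i for i in range(len(rows))}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            parent[find(i)] = find(j)

        by_identifier: Dict[str, List[int]] = {}
        for i, r in enumerate(rows):
            by_identifier.setdefault(r["identifier"], []).append(i)
        for group in by_identifier.values():
            for i in group[1:]:
                union(group[0], i)
        # chain link: child record's identifier equals a parent-domain pseudonym
        for i, r in enumerate(rows):
            dom_parent = self.engine.tree.get(r["domain"]).parent
            if dom_parent is None:
                continue
            j = key.get((dom_parent, r["identifier"]))
            if j is not None:
                union(i, j)

        source_idx = key.get((source_domain, source_pseudonym))
        if source_idx is None:
            raise NotFoundError("unknown source pseudonym",
                                reason="unknown-source-pseudonym")
        root = find(source_idx)
        return sorted(r["pseudonym"] for i, r in enumerate(rows)
                      if r["domain"] == target_domain and find(i) == root)

    # -- request dispatch -------------------------------------------------

    def handle(self, request: Request,
               principal: Optional[Principal] = None) -> Response:
        """Authorize, dispatch, serialize.  Errors map onto status codes."""
        route = None
        path_params: dict = {}
        for ep in ENDPOINTS:
            if ep.method != request.method:
                continue
            m = _match(ep.path, request.path)
            if m is not None:
                route = ep
                path_params = m
                break
        if route is None:
            return self._error(request, NotFoundError("no such endpoint"), 404)

        if route.path == "/ping":
            return self._respond(request, 200, {"status": "ok"}, text="pong")

        params = {**request.params, **path_params}
        domain = params.get("domain") or params.get("name") or ""
        if principal is None:
            return self._error(request,
                               UnauthorizedError("authentication required"), 401)
        if route.path == "/domains/linked-pseudonyms":
            # per-domain checks happen inside linked_pseudonyms (source+target)
            try:
                return self._dispatch(route, request, params, domain, principal)
            except UnauthorizedError as err:
                return self._error(request, err, 403)
            except PseudokitError as err:
                return self._error(request, err, _status_for(err))
        if not authorize(principal, route.action_class, domain):
            return self._error(
                request, UnauthorizedError(
                    f"{route.action_class} on {domain!r} denied"), 403)
        try:
            return self._dispatch(route, request, params, domain, principal)
        except PseudokitError as err:
            return self._error(request, err, _status_for(err))

    def _dispatch(self, route: EndpointDescriptor, request: Request,
                  params: dict, domain: str,
                  principal: Principal) -> Response:
        eng = self.engine
        actor, a_class = principal.user, principal.actor_class
        method, path = route.method, route.path

        if path in ("/domain", "/domain/privileged"):
            if method == "POST":
                cfg = eng.create_domain(
                    domain, spec=params.get("spec"),
                    parent=params.get("parent"),
                    privileged=route.privileged, actor=actor,
                    actor_class=a_class)
                return self._respond(request, 201,
                                     eng.tree.export_config(cfg.name),
                                     text=cfg.name)
            if method == "GET":
                cfg = eng.get_domain(domain, actor=actor, actor_class=a_class)
                return self._respond(request, 200,
                                     eng.tree.export_config(cfg.name),
                                     text=cfg.name)
            if method == "PUT":
                affected = eng.update_domain(
                    domain, params.get("changes", {}),
                    propagate=bool(params.get("propagate")),
                    privileged=route.privileged, actor=actor,
                    actor_class=a_class)
                body = {dom: sorted(attrs) for dom, attrs in affected.items()}
                return self._respond(request, 200, body,
                                     text=",".join(sorted(body)))
            if method == "DELETE":
                eng.delete_domain(domain, actor=actor, actor_class=a_class)
                return self._respond(request, 200, {"deleted": domain},
                                     text=domain)

        if path == "/domains/{domain}/salt":
            eng.set_domain_salt(domain, params["salt"], actor=actor,
                                actor_class=a_class)
            return self._respond(request, 200, {"domain": domain}, text=domain)

        if path == "/domains/linked-pseudonyms":
            linked = self.linked_pseudonyms(
                params["source_pseudonym"], params["source_domain"],
                params["target_domain"], principal)
            return self._respond(request, 200, {"pseudonyms": linked},
                                 text="\n".join(linked))

        if path in ("/domains/{domain}/pseudonym",
                    "/domains/{domain}/pseudonym/privileged"):
            if method == "POST":
                rec = eng.put_record(domain, params["identifier"],
                                     validity=params.get("validity"),
                                     actor=actor, actor_class=a_class)
                return self._respond(request, 201,
                                     {"identifier": rec.identifier,
                                      "pseudonym": rec.pseudonym},
                                     text=rec.pseudonym)
            if method == "GET":
                direction = params.get("direction", "identifier->pseudonym")
                rec = eng.resolve(domain, params["key"], direction=direction,
                                  at_time=params.get("at_time"),
                                  actor=actor, actor_class=a_class)
                value = (rec.pseudonym if direction == "identifier->pseudonym"
                         else rec.identifier)
                return self._respond(request, 200,
                                     {"identifier": rec.identifier,
                                      "pseudonym": rec.pseudonym},
                                     text=value)
            if method == "PUT":
                rec = eng.update_record(domain, params["pseudonym"],
                                        params.get("changes", {}),
                                        privileged=route.privileged,
                                        actor=actor, actor_class=a_class)
                return self._respond(request, 200,
                                     {"pseudonym": rec.pseudonym},
                                     text=rec.pseudonym)
            if method == "DELETE":
                eng.delete_record(domain, params["pseudonym"], actor=actor,
                                  actor_class=a_class)
                return self._respond(request, 200,
                                     {"deleted": params["pseudonym"]},
                                     text=params["pseudonym"])

        if path == "/domains/{domain}/{attribute}":
            value, inherited = eng.get_domain_attribute(
                domain, params["attribute"],
                privileged=bool(params.get("privileged")),
                actor=actor, actor_class=a_class)
            if isinstance(value, datetime):
                value = value.isoformat()
            elif not isinstance(value, (str, int, float, bool, type(None))):
                value = getattr(value, "name", str(value))
            return self._respond(request, 200,
                                 {"attribute": params["attribute"],
                                  "value": value, "inherited": inherited},
                                 text=str(value))

        if path == "/domains/{domain}/pseudonyms":
            op = {"POST": "create", "GET": "read", "PUT": "update",
                  "DELETE": "delete"}[method]
            results = eng.batch_ops(domain, op, params["items"],
                                    actor=actor, actor_class=a_class)
            text = "\n".join(str(r.get("value", r.get("error")))
                             for r in results)
            return self._respond(request, 200, {"results": results}, text=text)

        raise ValidationError(f"unhandled route {method} {path}")

    # -- serialisation ----------------------------------------------------

    def _respond(self, request: Request, status: int, body: dict,
                 text: str) -> Response:
        if request.accept == "text":
            return Response(status, text, "text/plain")
        return Response(status, body, "application/json")

    def _error(self, request: Request, err: PseudokitError,
               status: int) -> Response:
        body = {"error": err.code, "message": str(err), **err.context}
        if request.accept == "text":
            return Response(status, f"{err.code}: {err}", "text/plain")
        return Response(status, body, "application/json")


__all__ = [
    "Principal", "authorize", "StaticTokenAuthenticator",
    "EndpointDescriptor", "ENDPOINTS", "Request", "Response", "Service",
    "ACTION_CLASSES",
]
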