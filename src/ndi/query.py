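"""Composable query predicates over stored documents.

A query is a tree: leaves test one dot-path field (string match, numeric
comparison, field presence, schema membership, or dependency), and internal
nodes combine children with AND/OR.  Evaluation is pure — the same store
state and query always produce the same id-sorted result list.

Dot paths address the document's core fields and body fields uniformly
(body keys are visible at the top level; ``app.name`` reaches into nested
objects).  When a path traverses a list, the leaf matches if any member
matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import QueryError

LEAF_OPS = (
    "exact_string", "contains_string", "regexp",
    "exact_number", "greaterthan", "greaterthan_eq", "lessthan", "lessthan_eq",
    "hasfield", "isa", "depends_on",
)


@dataclass(frozen=True)
class Query:
    """Either a leaf (``op`` set) or a combinator (``combinator`` set)."""

    op: str | None = None
    field: str | None = None
    param: object = None
    combinator: str | None = None
    children: tuple = ()

    def __and__(self, other: "Query") -> "Query":
        return q_and(self, other)

    def __or__(self, other: "Query") -> "Query":
        return q_or(self, other)


def _leaf(op, fieldname, param) -> Query:
    if op not in LEAF_OPS:
        raise QueryError(f"unknown query op {op!r}")
    return Query(op=op, field=fieldname, param=param)


def q_exact(fieldname: str, value: str) -> Query:
    return _leaf("exact_string", fieldname, value)


def q_contains(fieldname: str, value: str) -> Query:
    return _leaf("contains_string", fieldname, value)


def q_regexp(fieldname: str, pattern: str) -> Query:
    try:
        re.compile(pattern)
    except re.error as exc:
        raise QueryError(f"invalid regexp {pattern!r}: {exc}") from exc
    return _leaf("regexp", fieldname, pattern)


def q_number(fieldname: str, value) -> Query:
    return _leaf("exact_number", fieldname, value)


def q_gt(fieldname: str, value) -> Query:
    return _leaf("greaterthan", fieldname, value)


def q_ge(fieldname: str, value) -> Query:
    return _leaf("greaterthan_eq", fieldname, value)


def q_lt(fieldname: str, value) -> Query:
    return _leaf("lessthan", fieldname, value)


def q_le(fieldname: str, value) -> Query:
    return _leaf("lessthan_eq", fieldname, value)


def q_hasfield(fieldname: str) -> Query:
    return _leaf("hasfield", fieldname, None)


def q_isa(schema_name: str) -> Query:
    return _leaf("isa", None, schema_name)


def q_depends_on(name: str, doc_id: str) -> Query:
    """Dependency leaf; ``name == ""`` matches any dependency name."""
    return _leaf("depends_on", None, (name, doc_id))


def q_and(*children: Query) -> Query:
    if not children:
        raise QueryError("AND needs at least one child")
    return Query(combinator="AND", children=tuple(children))


def q_or(*children: Query) -> Query:
    if not children:
        raise QueryError("OR needs at least one child")
    return Query(combinator="OR", children=tuple(children))


# ---------------------------------------------------------------------------


def resolve_path(doc: dict, path: str) -> list:
    """All values at ``path``; lists fan out to their members."""
    view = {k: v for k, v in doc.items() if k != "body"}
    view.update(doc.get("body", {}))
    values = [view]
    for part in path.split("."):
        nxt = []
        for val in values:
            if isinstance(val, list):
                val_items = val
            else:
                val_items = [val]
            for item in val_items:
                if isinstance(item, dict) and part in item:
                    nxt.append(item[part])
        values = nxt
        if not values:
            return []
    flat = []
    for val in values:
        if isinstance(val, list):
            flat.extend(val)
        else:
            flat.append(val)
    return flat


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def match_leaf(doc: dict, q: Query, registry=None) -> bool:
    op = q.op
    if op == "isa":
        name = doc.get("schema", {}).get("name")
        if name is None:
            return False
        if registry is not None and name in registry:
            return registry.isa(name, q.param)
        return name == q.param
    if op == "depends_on":
        want_name, want_id = q.param
        for dep in doc.get("depends_on", []):
            if dep.get("value") == want_id and (
                want_name == "" or dep.get("name") == want_name
            ):
                return True
        return False
    values = resolve_path(doc, q.field)
    if op == "hasfield":
        return bool(values)
    for v in values:
        if op == "exact_string":
            if isinstance(v, str) and v == q.param:
                return True
        elif op == "contains_string":
            if isinstance(v, str) and str(q.param) in v:
                return True
        elif op == "regexp":
            if isinstance(v, str) and re.search(q.param, v):
                return True
        elif op == "exact_number":
            if _is_number(v) and v == q.param:
                return True
        elif op == "greaterthan":
            if _is_number(v) and v > q.param:
                return True
        elif op == "greaterthan_eq":
            if _is_number(v) and v >= q.param:
                return True
        elif op == "lessthan":
            if _is_number(v) and v < q.param:
                return True
        elif op == "lessthan_eq":
            if _is_number(v) and v <= q.param:
                return True
        else:  # pragma: no cover - constructors reject unknown ops
            raise QueryError(f"unknown query op {op!r}")
    return False


def matches(doc: dict, q: Query, registry=None) -> bool:
    if q.combinator == "AND":
        return all(matches(doc, c, registry) for c in q.children)
    if q.combinator == "OR":
        return any(matches(doc, c, registry) for c in q.children)
    return match_leaf(doc, q, registry)


def evaluate(store, q: Query) -> list[str]:
    """Ids of all documents in ``store`` matching ``q``, id-sorted."""
    registry = getattr(store, "schemas", None)
    return sorted(
        doc["id"] for doc in store.documents() if matches(doc, q, registry)
    )
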