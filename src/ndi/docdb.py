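"""Directory-backed document store with composable schemas and dependencies.

Every analysis artifact — a subject, a probe, extraction parameters, spike
waveforms, a tuning curve — is a *document*: a JSON record carrying five core
fields (session id, document id, schema name+version, UTC creation timestamp,
and a list of named dependencies on other documents) plus schema-specific
body fields and an optional binary blob stored in a sidecar file.

Schemas compose: a schema lists superclasses whose fields it inherits, so a
``spikewaves`` document must also satisfy the generic document, epoch-id and
app schemas.  Dependencies are checked at insert time, which makes the
dependency graph a DAG by construction and lets any derived result be traced
back to the raw data it came from.
"""

from __future__ import annotations

import datetime as _dt
import json
import shutil
from importlib import resources
from pathlib import Path

import networkx as nx

from .errors import (
    DependencyError,
    SchemaError,
    UnknownDocumentError,
    ValidationError,
)
from .ids import new_identifier

CORE_FIELDS = ("id", "session_id", "schema", "timestamp", "depends_on")

_KIND_CHECKS = {
    "string": lambda v: isinstance(v, str),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "list": lambda v: isinstance(v, list),
    "object": lambda v: isinstance(v, dict),
}


def utc_timestamp() -> str:
    """Current UTC time, ISO-8601 with millisecond precision."""
    now = _dt.datetime.now(_dt.timezone.utc)
    return now.strftime("%Y-%m-%dT%H:%M:%S.") + f"{now.microsecond // 1000:03d}Z"


class SchemaRegistry:
    """Resolves schema composition (superclass field inheritance)."""

    def __init__(self):
        self._defs: dict[str, dict] = {}
        self._effective: dict[str, dict] = {}

    def register(self, definition: dict) -> None:
        name = definition.get("name")
        if not name or not isinstance(name, str):
            raise SchemaError("schema definition needs a string 'name'")
        supers = definition.get("superclasses", [])
        fields = definition.get("fields", {})
        effective: dict[str, dict] = {}
        for sup in supers:
            if sup not in self._defs:
                raise SchemaError(f"schema {name!r}: unknown superclass {sup!r}")
            for fname, spec in self._effective[sup].items():
                if fname in effective and effective[fname]["kind"] != spec["kind"]:
                    raise SchemaError(
                        f"schema {name!r}: field {fname!r} inherited with "
                        f"conflicting kinds"
                    )
                effective.setdefault(fname, dict(spec))
                if spec.get("required"):
                    effective[fname]["required"] = True
        for fname, spec in fields.items():
            kind = spec.get("kind")
            if kind not in _KIND_CHECKS:
                raise SchemaError(f"schema {name!r}: field {fname!r} bad kind {kind!r}")
            if fname in effective and effective[fname]["kind"] != kind:
                raise SchemaError(
                    f"schema {name!r}: field {fname!r} collides with an "
                    f"inherited field of a different kind"
                )
            effective[fname] = {"kind": kind, "required": bool(spec.get("required"))}
        self._defs[name] = definition
        self._effective[name] = effective

    def __contains__(self, name) -> bool:
        return name in self._defs

    def names(self) -> list[str]:
        return sorted(self._defs)

    def definition(self, name: str) -> dict:
        if name not in self._defs:
            raise SchemaError(f"unknown schema {name!r}")
        return self._defs[name]

    def effective_fields(self, name: str) -> dict:
        if name not in self._effective:
            raise SchemaError(f"unknown schema {name!r}")
        return self._effective[name]

    def ancestors(self, name: str) -> set[str]:
        """All (transitive) superclasses of ``name``, excluding itself."""
        out: set[str] = set()
        stack = list(self._defs.get(name, {}).get("superclasses", []))
        while stack:
            sup = stack.pop()
            if sup not in out:
                out.add(sup)
                stack.extend(self._defs.get(sup, {}).get("superclasses", []))
        return out

    def isa(self, name: str, ancestor: str) -> bool:
        return name == ancestor or ancestor in self.ancestors(name)


def load_builtin_schemas(registry: SchemaRegistry) -> None:
    """Register the schemas shipped with the package (dependency order)."""
    root = resources.files("ndi") / "schemas"
    defs = {}
    for entry in root.iterdir():
        if entry.name.endswith(".json"):
            defs[entry.name[:-5]] = json.loads(entry.read_text())
    pending = dict(defs)
    while pending:
        progressed = False
        for name in sorted(pending):
            definition = pending[name]
            if all(s in registry for s in definition.get("superclasses", [])):
                registry.register(definition)
                del pending[name]
                progressed = True
        if not progressed:  # pragma: no cover - shipped schemas are consistent
            raise SchemaError(f"unresolvable schema superclasses: {sorted(pending)}")


def new_document(schema: str, session_id: str, body: dict | None = None,
                 depends_on: list[dict] | None = None) -> dict:
    """Assemble a document dict with fresh core fields."""
    return {
        "id": new_identifier(),
        "session_id": session_id,
        "schema": {"name": schema, "version": 1},
        "timestamp": utc_timestamp(),
        "depends_on": [dict(d) for d in (depends_on or [])],
        "body": dict(body or {}),
    }


def validate_document(registry: SchemaRegistry, doc: dict) -> None:
    """Raise ValidationError listing every missing or mistyped field."""
    problems = []
    if not isinstance(doc, dict):
        raise ValidationError("document must be a mapping")
    schema = doc.get("schema")
    if not isinstance(schema, dict) or "name" not in schema:
        problems.append("core field 'schema' must be {'name', 'version'}")
        raise ValidationError("invalid document", problems)
    name = schema["name"]
    if name not in registry:
        raise ValidationError(f"unknown schema {name!r}", [f"schema {name!r}"])
    body = doc.get("body", {})
    if not isinstance(body, dict):
        problems.append("'body' must be an object")
        body = {}
    for fname, spec in registry.effective_fields(name).items():
        container = doc if fname in CORE_FIELDS else body
        if fname not in container:
            if spec["required"]:
                problems.append(f"missing required field {fname!r}")
            continue
        if not _KIND_CHECKS[spec["kind"]](container[fname]):
            problems.append(f"field {fname!r} is not of kind {spec['kind']!r}")
    deps = doc.get("depends_on")
    if isinstance(deps, list):
        for i, dep in enumerate(deps):
            if (not isinstance(dep, dict) or "name" not in dep
                    or "value" not in dep):
                problems.append(f"depends_on[{i}] must have 'name' and 'value'")
    if problems:
        raise ValidationError(
            "document failed validation: " + "; ".join(problems), problems
        )


class DocumentStore:
    """One JSON file per document plus blob sidecars under a root directory.

    An in-memory index (by id, by schema, dependency adjacency) is rebuilt
    when the store is opened.
    """

    def __init__(self, root):
        self.root = Path(root)
        self.docs_dir = self.root / "documents"
        self.blobs_dir = self.root / "blobs"
        self.schemas_dir = self.root / "schemas"
        for d in (self.docs_dir, self.blobs_dir, self.schemas_dir):
            d.mkdir(parents=True, exist_ok=True)
        self.schemas = SchemaRegistry()
        load_builtin_schemas(self.schemas)
        self._load_user_schemas()
        self._docs: dict[str, dict] = {}
        self._dependents: dict[str, set[str]] = {}
        self._by_schema: dict[str, set[str]] = {}
        self._reindex()

    # -- schemas ---------------------------------------------------------
    def _load_user_schemas(self):
        pending = {}
        for path in sorted(self.schemas_dir.glob("*.json")):
            defn = json.loads(path.read_text())
            pending[defn["name"]] = defn
        while pending:
            progressed = False
            for name in sorted(pending):
                defn = pending[name]
                if all(s in self.schemas for s in defn.get("superclasses", [])):
                    self.schemas.register(defn)
                    del pending[name]
                    progressed = True
            if not progressed:
                raise SchemaError(
                    f"stored schemas have unresolvable superclasses: "
                    f"{sorted(pending)}"
                )

    def register_schema(self, definition: dict, persist: bool = True) -> None:
        self.schemas.register(definition)
        if persist:
            path = self.schemas_dir / f"{definition['name']}.json"
            path.write_text(json.dumps(definition, indent=1, sort_keys=True))

    # -- indexing --------------------------------------------------------
    def _reindex(self):
        self._docs.clear()
        self._dependents.clear()
        self._by_schema.clear()
        for path in sorted(self.docs_dir.glob("*.json")):
            doc = json.loads(path.read_text())
            self._index(doc)

    def _index(self, doc):
        did = doc["id"]
        self._docs[did] = doc
        self._by_schema.setdefault(doc["schema"]["name"], set()).add(did)
        for dep in doc.get("depends_on", []):
            self._dependents.setdefault(dep["value"], set()).add(did)

    # -- CRUD ------------------------------------------------------------
    def add(self, doc: dict, blob: bytes | None = None) -> str:
        validate_document(self.schemas, doc)
        did = doc["id"]
        if did in self._docs:
            raise ValidationError(f"document {did} already exists")
        dangling = [d["value"] for d in doc.get("depends_on", [])
                    if d["value"] not in self._docs]
        if dangling:
            raise DependencyError(
                f"document {did} depends on nonexistent documents: {dangling}"
            )
        (self.docs_dir / f"{did}.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True)
        )
        if blob is not None:
            (self.blobs_dir / f"{did}.bin").write_bytes(blob)
        self._index(doc)
        return did

    def get(self, doc_id: str) -> dict:
        if doc_id not in self._docs:
            raise UnknownDocumentError(f"no document {doc_id}")
        return self._docs[doc_id]

    def get_blob(self, doc_id: str) -> bytes | None:
        self.get(doc_id)
        path = self.blobs_dir / f"{doc_id}.bin"
        return path.read_bytes() if path.exists() else None

    def __contains__(self, doc_id) -> bool:
        return doc_id in self._docs

    def __len__(self) -> int:
        return len(self._docs)

    def all_ids(self) -> list[str]:
        return sorted(self._docs)

    def documents(self):
        for did in self.all_ids():
            yield self._docs[did]

    def dependents_closure(self, doc_id: str) -> list[str]:
        """Transitive dependents of ``doc_id`` (excluding itself),
        dependents-first (topological) order."""
        self.get(doc_id)
        return self._closure_dependents_first(doc_id)

    def remove(self, doc_id: str, policy: str = "refuse_if_dependents") -> list[str]:
        self.get(doc_id)
        closure = self._closure_dependents_first(doc_id)
        if closure and policy == "refuse_if_dependents":
            raise DependencyError(
                f"cannot remove {doc_id}: documents depend on it: {closure}"
            )
        if policy not in ("refuse_if_dependents", "cascade"):
            raise ValueError(f"unknown removal policy {policy!r}")
        removed = (closure if policy == "cascade" else []) + [doc_id]
        for did in removed:
            (self.docs_dir / f"{did}.json").unlink()
            blob = self.blobs_dir / f"{did}.bin"
            if blob.exists():
                blob.unlink()
        self._reindex()
        return removed

    def _closure_dependents_first(self, doc_id: str) -> list[str]:
        sub = {doc_id}
        stack = [doc_id]
        while stack:
            cur = stack.pop()
            for child in self._dependents.get(cur, ()):
                if child not in sub:
                    sub.add(child)
                    stack.append(child)
        sub.discard(doc_id)
        if not sub:
            return []
        g = nx.DiGraph()
        g.add_nodes_from(sub)
        for did in sub:
            for dep in self._docs[did].get("depends_on", []):
                if dep["value"] in sub:
                    g.add_edge(did, dep["value"])  # dependent -> dependency
        return list(nx.topological_sort(g))

    # -- graph -----------------------------------------------------------
    def dependency_graph(self, session_id: str | None = None) -> nx.DiGraph:
        """Directed graph: edge dependent -> dependency."""
        g = nx.DiGraph()
        for doc in self.documents():
            if session_id and doc["session_id"] != session_id:
                continue
            g.add_node(doc["id"], schema=doc["schema"]["name"])
        for doc in self.documents():
            if doc["id"] not in g:
                continue
            for dep in doc.get("depends_on", []):
                if dep["value"] in g:
                    g.add_edge(doc["id"], dep["value"], name=dep["name"])
        return g

    def find(self, query) -> list[str]:
        from .query import evaluate

        return evaluate(self, query)

    def destroy(self):  # pragma: no cover - test utility
        shutil.rmtree(self.root)


def graph_to_dot(g: nx.DiGraph) -> str:
    """Render a dependency graph in DOT format."""
    lines = ["digraph documents {"]
    for node in sorted(g.nodes):
        label = g.nodes[node].get("schema", "")
        lines.append(f'  "{node}" [label="{label}\\n{node[:12]}"];')
    for u, v in sorted(g.edges):
        name = g.edges[u, v].get("name", "")
        lines.append(f'  "{u}" -> "{v}" [label="{name}"];')
    lines.append("}")
    return "\n".join(lines)


def graph_to_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)
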