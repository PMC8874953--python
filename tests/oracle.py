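"""Independent brute-force query evaluator used as the test oracle.

Reads raw document JSON straight from the store directory and implements
the predicate semantics from scratch (no shared code with the store's
evaluator beyond the Query dataclass it interprets).
"""

import json
import re
from pathlib import Path


def _load_schema_defs():
    from importlib import resources

    defs = {}
    for entry in (resources.files("ndi") / "schemas").iterdir():
        if entry.name.endswith(".json"):
            d = json.loads(entry.read_text())
            defs[d["name"]] = d
    return defs


_SCHEMAS = _load_schema_defs()


def _ancestors(name):
    out, stack = set(), [name]
    while stack:
        cur = stack.pop()
        for sup in _SCHEMAS.get(cur, {}).get("superclasses", []):
            if sup not in out:
                out.add(sup)
                stack.append(sup)
    return out


def _values_at(obj, parts):
    if not parts:
        if isinstance(obj, list):
            return list(obj)
        return [obj]
    head, rest = parts[0], parts[1:]
    results = []
    if isinstance(obj, dict):
        if head in obj:
            results.extend(_values_at(obj[head], rest))
    elif isinstance(obj, list):
        for item in obj:
            results.extend(_values_at(item, parts))
    return results


def _lookup(doc, path):
    merged = {k: v for k, v in doc.items() if k != "body"}
    merged.update(doc.get("body", {}))
    return _values_at(merged, path.split("."))


def _num(v):
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def _leaf_matches(doc, q):
    if q.op == "isa":
        name = doc["schema"]["name"]
        return name == q.param or q.param in _ancestors(name)
    if q.op == "depends_on":
        want_name, want_id = q.param
        return any(
            d["value"] == want_id and (want_name in ("", d["name"]))
            for d in doc.get("depends_on", [])
        )
    vals = _lookup(doc, q.field)
    if q.op == "hasfield":
        return len(vals) > 0
    for v in vals:
        if q.op == "exact_string" and isinstance(v, str) and v == q.param:
            return True
        if q.op == "contains_string" and isinstance(v, str) and q.param in v:
            return True
        if q.op == "regexp" and isinstance(v, str) and re.search(q.param, v):
            return True
        if q.op == "exact_number" and _num(v) and v == q.param:
            return True
        if q.op == "greaterthan" and _num(v) and v > q.param:
            return True
        if q.op == "greaterthan_eq" and _num(v) and v >= q.param:
            return True
        if q.op == "lessthan" and _num(v) and v < q.param:
            return True
        if q.op == "lessthan_eq" and _num(v) and v <= q.param:
            return True
    return False


def _matches(doc, q):
    if q.combinator == "AND":
        return all(_matches(doc, c) for c in q.children)
    if q.combinator == "OR":
        return any(_matches(doc, c) for c in q.children)
    return _leaf_matches(doc, q)


def evaluate_by_scan(store_root, q):
    """Evaluate a query by linear scan over the JSON files on disk."""
    hits = []
    for path in Path(store_root, "documents").glob("*.json"):
        doc = json.loads(path.read_text())
        if _matches(doc, q):
            hits.append(doc["id"])
    return sorted(hits)


# ---------------------------------------------------------------------------
# random stores and random queries for equivalence testing


WORDS = ["alpha", "beta", "gamma", "delta", "spike", "cortex", "stim",
         "Extract", "wave9"]


def random_store(store, rng, n_docs=500):
    """Populate ``store`` with a mix of schemas, values, and dependencies."""
    from ndi.docdb import new_document

    ids = []
    for i in range(n_docs):
        kind = rng.integers(0, 3)
        deps = []
        if ids and rng.random() < 0.5:
            k = int(rng.integers(0, len(ids)))
            deps.append({"name": str(rng.choice(["element_id", "params_id", ""])) or "x",
                         "value": ids[k]})
        if kind == 0:
            body = {"local_id": str(rng.choice(WORDS)) + str(rng.integers(0, 5)),
                    "description": " ".join(rng.choice(WORDS, size=3))}
            doc = new_document("subject", f"sess{rng.integers(0, 3)}", body, deps)
        elif kind == 1:
            body = {
                "app": {"name": str(rng.choice(WORDS)),
                        "version": str(rng.integers(0, 4))},
                "oi": float(np.round(rng.uniform(-1, 2), 3)),
                "di": float(np.round(rng.uniform(-1, 2), 3)),
                "fit": {"sigma": float(np.round(rng.uniform(1, 90), 2)),
                        "theta_pref": float(rng.integers(0, 360))},
                "fit_residual": float(np.round(rng.uniform(0, 5), 3)),
            }
            doc = new_document("oridir_tuning", f"sess{rng.integers(0, 3)}",
                               body, deps)
        else:
            dirs = [float(d) for d in range(0, 360, 90)]
            body = {"directions": dirs,
                    "mean": [float(np.round(rng.uniform(-1, 20), 2))
                             for _ in dirs],
                    "sem": [0.1] * len(dirs),
                    "n": [int(rng.integers(1, 9)) for _ in dirs]}
            doc = new_document("tuning_curve", f"sess{rng.integers(0, 3)}",
                               body, deps)
        ids.append(store.add(doc))
    return ids


import numpy as np  # noqa: E402  (used by random_store)

FIELDS = ["local_id", "description", "app.name", "app.version", "oi", "di",
          "fit.sigma", "fit.theta_pref", "mean", "n", "session_id",
          "schema.name", "nonexistent.field"]
REGEXES = [r"^alpha", r"a.*a", r"\d$", r"spike|wave", r"[A-Z]"]
SCHEMAS = ["subject", "oridir_tuning", "tuning_curve", "ndi_document",
           "ndi_app", "spikewaves"]


def random_query(rng, ids, depth=0):
    from ndi import query as q

    roll = rng.random()
    if depth < 2 and roll < 0.3:
        n = int(rng.integers(1, 4))
        children = [random_query(rng, ids, depth + 1) for _ in range(n)]
        return (q.q_and if rng.random() < 0.5 else q.q_or)(*children)
    op = rng.choice(["exact_string", "contains_string", "regexp",
                     "exact_number", "greaterthan", "greaterthan_eq",
                     "lessthan", "lessthan_eq", "hasfield", "isa",
                     "depends_on"])
    fieldname = str(rng.choice(FIELDS))
    if op == "isa":
        return q.q_isa(str(rng.choice(SCHEMAS)))
    if op == "depends_on":
        name = str(rng.choice(["element_id", "params_id", "x", ""]))
        return q.q_depends_on(name, str(rng.choice(ids)))
    if op == "hasfield":
        return q.q_hasfield(fieldname)
    if op in ("exact_string", "contains_string"):
        param = str(rng.choice(WORDS + ["sess1", "zzz"]))
        ctor = q.q_exact if op == "exact_string" else q.q_contains
        return ctor(fieldname, param)
    if op == "regexp":
        return q.q_regexp(fieldname, str(rng.choice(REGEXES)))
    param = float(np.round(rng.uniform(-1, 20), 2))
    ctor = {"exact_number": q.q_number, "greaterthan": q.q_gt,
            "greaterthan_eq": q.q_ge, "lessthan": q.q_lt,
            "lessthan_eq": q.q_le}[op]
    return ctor(fieldname, param)
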