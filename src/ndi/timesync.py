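"""Clocks, time references, affine time mappings, and the sync graph.

Different acquisition devices keep different clocks, so a bare timestamp is
meaningless: every time in this package travels with a
:class:`TimeReference` naming the item it refers to, the clock type, the
epoch (for device-local clocks), and an offset.  Conversion between time
bases is solved on a directed graph whose nodes are (item, epoch, clock
type) triples and whose edges carry invertible affine maps
``t_target = scale * t_source + shift``.  Edges come from three sources:

* *sync rules* — e.g. a regression over digital triggers recorded in common
  by two DAQ systems;
* *inheritance* — a probe or derived element shares the epochs (and clock)
  of the item underneath it, an identity map;
* *same units* — any two nodes on the same global clock (UTC, or an
  experiment-wide global clock) are identity-linked.

When no path exists between two nodes the conversion legitimately fails
with :class:`~ndi.errors.NoTimeMappingError`: e.g. two devices with only
local clocks and no shared signal have unknowable relative timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import networkx as nx
import numpy as np

from .errors import NoTimeMappingError


class ClockType(str, Enum):
    NO_TIME = "no_time"
    DEV_LOCAL_TIME = "dev_local_time"
    DEV_GLOBAL_TIME = "dev_global_time"
    EXP_GLOBAL_TIME = "exp_global_time"
    UTC = "utc"

    @property
    def is_global(self) -> bool:
        return self in (ClockType.EXP_GLOBAL_TIME, ClockType.UTC)


def as_clocktype(value) -> ClockType:
    return value if isinstance(value, ClockType) else ClockType(value)


@dataclass(frozen=True)
class TimeMapping:
    """Affine map ``t_target = scale * t_source + shift`` (scale > 0)."""

    scale: float = 1.0
    shift: float = 0.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("TimeMapping scale must be positive")

    def apply(self, t):
        return self.scale * np.asarray(t) + self.shift if hasattr(t, "__len__") \
            else self.scale * t + self.shift

    __call__ = apply

    def inverse(self) -> "TimeMapping":
        return TimeMapping(1.0 / self.scale, -self.shift / self.scale)

    def then(self, other: "TimeMapping") -> "TimeMapping":
        """Composition: first apply self, then ``other``."""
        return TimeMapping(other.scale * self.scale,
                           other.scale * self.shift + other.shift)


IDENTITY = TimeMapping(1.0, 0.0)


@dataclass(frozen=True)
class TimeReference:
    """Disambiguates a timestamp: (referent item, clock type, epoch, offset).

    A time ``t`` under this reference corresponds to device/clock time
    ``t - offset`` on the referent's named epoch clock.
    """

    referent: str
    clocktype: ClockType
    epoch_id: str | None = None
    offset: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "clocktype", as_clocktype(self.clocktype))
        if self.clocktype == ClockType.DEV_LOCAL_TIME and self.epoch_id is None:
            raise ValueError("device-local time reference requires an epoch_id")


# ---------------------------------------------------------------------------
# sync rules


@dataclass(frozen=True)
class SyncRule:
    """Declarative recipe proposing mappings between epochs of two DAQs.

    ``shared_triggers``: both DAQ systems recorded the same digital trigger
    train; a regression of one train on the other yields the mapping, and
    the rule abstains when the fit residual exceeds ``tolerance``.
    ``shared_file``: the two DAQ systems share an epoch file, hence a clock
    (identity mapping).
    """

    kind: str
    daq_a: str
    channel_a: str
    daq_b: str
    channel_b: str
    tolerance: float = 1e-3

    @classmethod
    def from_config(cls, cfg: dict) -> "SyncRule":
        return cls(
            kind=cfg["kind"],
            daq_a=cfg["daq_a"],
            channel_a=cfg.get("channel_a", ""),
            daq_b=cfg["daq_b"],
            channel_b=cfg.get("channel_b", ""),
            tolerance=float(cfg.get("tolerance", 1e-3)),
        )


def _match_by_intervals(short: np.ndarray, long: np.ndarray):
    """Align a shorter trigger train inside a longer one.

    Slides the shorter inter-trigger-interval sequence over the longer and
    returns the offset with minimal summed absolute interval difference,
    or None when the minimum is not unique.
    """
    ds, dl = np.diff(short), np.diff(long)
    n_pos = len(dl) - len(ds) + 1
    costs = np.array(
        [np.abs(dl[k : k + len(ds)] - ds).sum() for k in range(n_pos)]
    )
    order = np.argsort(costs)
    if len(costs) > 1 and costs[order[1]] - costs[order[0]] <= 1e-12:
        return None
    return int(order[0])


def estimate_mapping_shared_triggers(times_a, times_b, tolerance: float):
    """Least-squares affine fit ``t_b = scale * t_a + shift`` from triggers.

    Returns ``(TimeMapping, rms_residual)`` or ``None`` (abstain) when either
    train has fewer than two triggers, the trains cannot be aligned, or the
    fit residual exceeds ``tolerance``.
    """
    a = np.sort(np.asarray(times_a, dtype=float))
    b = np.sort(np.asarray(times_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        return None
    if len(a) != len(b):
        if len(a) < len(b):
            k = _match_by_intervals(a, b)
            if k is None:
                return None
            b = b[k : k + len(a)]
        else:
            k = _match_by_intervals(b, a)
            if k is None:
                return None
            a = a[k : k + len(b)]
    scale, shift = np.polyfit(a, b, 1)
    if scale <= 0:
        return None
    resid = b - (scale * a + shift)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > tolerance:
        return None
    return TimeMapping(float(scale), float(shift)), rms


# ---------------------------------------------------------------------------
# the graph


def _node(item_key: str, epoch_id: str, clocktype: ClockType):
    return (item_key, epoch_id, as_clocktype(clocktype).value)


class SyncGraph:
    """Directed graph of (item, epoch, clock-type) nodes and affine edges.

    Every edge is stored with its reverse (inverse mapping), so the graph is
    symmetric as a reachability relation.
    """

    def __init__(self):
        self.g = nx.DiGraph()

    def add_node(self, item_key, epoch_id, clocktype):
        ct = as_clocktype(clocktype)
        if ct == ClockType.NO_TIME:
            return  # no_time nodes participate in no conversions
        self.g.add_node(_node(item_key, epoch_id, ct))

    def add_edge(self, src, dst, mapping: TimeMapping, provenance: str,
                 residual: float = 0.0):
        """Insert src->dst and the inverse dst->src edge.

        When an edge already exists between the pair, the one with the
        smaller residual wins.
        """
        if self.g.has_edge(src, dst) and \
                self.g.edges[src, dst]["residual"] <= residual:
            return
        self.g.add_edge(src, dst, mapping=mapping, provenance=provenance,
                        residual=residual)
        self.g.add_edge(dst, src, mapping=mapping.inverse(),
                        provenance=provenance, residual=residual)

    def nodes(self):
        return list(self.g.nodes)

    def has_node(self, item_key, epoch_id, clocktype) -> bool:
        return _node(item_key, epoch_id, clocktype) in self.g

    def link_same_units(self):
        """Identity-link all node pairs sharing a global clock type."""
        for ct in (ClockType.UTC, ClockType.EXP_GLOBAL_TIME):
            nodes = sorted(n for n in self.g.nodes if n[2] == ct.value)
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    self.add_edge(u, v, IDENTITY, "same_units")

    # -- path solving ------------------------------------------------------
    def _bfs(self, src):
        """Deterministic BFS: parents map, exploring neighbors in sorted order."""
        if src not in self.g:
            raise NoTimeMappingError(f"unknown time node {src}")
        parents = {src: None}
        depth = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in sorted(self.g.successors(u)):
                    if v not in parents:
                        parents[v] = u
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            frontier = nxt
        return parents, depth

    def path_mapping(self, src, target_item: str, target_clocktype) -> tuple:
        """Composed mapping from ``src`` to the nearest node of
        (target_item, target_clocktype); fewest edges, lexicographic
        tie-break.  Returns (mapping, target_node)."""
        ct = as_clocktype(target_clocktype).value
        parents, depth = self._bfs(src)
        candidates = [
            n for n in parents
            if n[0] == target_item and n[2] == ct
        ]
        if not candidates:
            raise NoTimeMappingError(
                f"no known time mapping from {src} to "
                f"({target_item}, {ct})"
            )
        target = min(candidates, key=lambda n: (depth[n], n))
        # walk back to src, composing forward
        chain = []
        cur = target
        while parents[cur] is not None:
            chain.append((parents[cur], cur))
            cur = parents[cur]
        mapping = IDENTITY
        for u, v in reversed(chain):
            mapping = mapping.then(self.g.edges[u, v]["mapping"])
        return mapping, target


def build_syncgraph(session, elements=None) -> SyncGraph:
    """Assemble the sync graph for a session.

    Nodes cover every (DAQ system, epoch, clock type); sync-rule edges are
    added for every epoch pair where the rule produces a mapping;
    inheritance identity edges connect probes/derived elements to their
    underlying items; same-units edges identity-link global clocks.
    """
    graph = SyncGraph()
    root = session.root
    daqs = {d.name: d for d in session.daq_systems()}
    epoch_tables = {name: d.epochs(root) for name, d in daqs.items()}

    for name, entries in epoch_tables.items():
        key = f"daq:{name}"
        for e in entries:
            for ct in e.clocktypes:
                graph.add_node(key, e.epoch_id, ct)
            if ClockType.UTC in e.clocktypes:
                anchor = daqs[name].utc_anchor(root, e.epoch_id)
                graph.add_edge(
                    _node(key, e.epoch_id, ClockType.DEV_LOCAL_TIME),
                    _node(key, e.epoch_id, ClockType.UTC),
                    TimeMapping(1.0, float(anchor)),
                    "inheritance",
                )

    for rule_cfg in session.syncrules():
        rule = rule_cfg if isinstance(rule_cfg, SyncRule) \
            else SyncRule.from_config(rule_cfg)
        if rule.daq_a not in daqs or rule.daq_b not in daqs:
            continue
        for ea in epoch_tables[rule.daq_a]:
            ta = [t for t, _ in daqs[rule.daq_a].read_events(
                root, ea.epoch_id, rule.channel_a)]
            for eb in epoch_tables[rule.daq_b]:
                if rule.kind == "shared_file":
                    shared = set(map(str, ea.files)) & set(map(str, eb.files))
                    if shared:
                        graph.add_edge(
                            _node(f"daq:{rule.daq_a}", ea.epoch_id,
                                  ClockType.DEV_LOCAL_TIME),
                            _node(f"daq:{rule.daq_b}", eb.epoch_id,
                                  ClockType.DEV_LOCAL_TIME),
                            IDENTITY, "syncrule",
                        )
                    continue
                tb = [t for t, _ in daqs[rule.daq_b].read_events(
                    root, eb.epoch_id, rule.channel_b)]
                est = estimate_mapping_shared_triggers(ta, tb, rule.tolerance)
                if est is None:
                    continue
                mapping, rms = est
                graph.add_edge(
                    _node(f"daq:{rule.daq_a}", ea.epoch_id,
                          ClockType.DEV_LOCAL_TIME),
                    _node(f"daq:{rule.daq_b}", eb.epoch_id,
                          ClockType.DEV_LOCAL_TIME),
                    mapping, "syncrule", residual=rms,
                )

    for el in elements or ():
        _add_element_inheritance(graph, el)

    graph.link_same_units()
    return graph


def _add_element_inheritance(graph: SyncGraph, element) -> None:
    """Identity-link an element's epochs to its underlying item's epochs."""
    under = element.underlying_key()
    for ep in element.epochs:
        for ct in ep.clocktypes:
            graph.add_node(element.item_key, ep.epoch_id, ct)
            if under is not None:
                graph.add_edge(
                    _node(element.item_key, ep.epoch_id, ct),
                    _node(under, ep.epoch_id, ct),
                    IDENTITY, "inheritance",
                )


def convert_time(graph: SyncGraph, t, ref_in: TimeReference,
                 target_referent: str, target_clocktype):
    """Convert ``t`` (scalar or array) to another item's clock.

    Returns ``(t_out, ref_out)``; raises
    :class:`~ndi.errors.NoTimeMappingError` when the graph has no path.
    """
    src = _resolve_source(graph, ref_in)
    mapping, target = graph.path_mapping(
        src, target_referent, target_clocktype
    )
    t_out = mapping.apply(np.asarray(t, dtype=float) - ref_in.offset)
    if np.isscalar(t) or np.ndim(t) == 0:
        t_out = float(t_out)
    ref_out = TimeReference(
        referent=target_referent,
        clocktype=as_clocktype(target_clocktype),
        epoch_id=target[1],
        offset=0.0,
    )
    return t_out, ref_out


def _resolve_source(graph: SyncGraph, ref: TimeReference):
    if ref.epoch_id is not None:
        src = _node(ref.referent, ref.epoch_id, ref.clocktype)
        if src not in graph.g:
            raise NoTimeMappingError(f"time reference {ref} is not in the graph")
        return src
    candidates = sorted(
        n for n in graph.g.nodes
        if n[0] == ref.referent and n[2] == ref.clocktype.value
    )
    if not candidates:
        raise NoTimeMappingError(f"time reference {ref} is not in the graph")
    return candidates[0]


def readtimeseries(graph: SyncGraph, item, ref_in: TimeReference,
                   t_i: float, t_j: float):
    """Read ``item`` over [t_i, t_j) expressed in ``ref_in``'s time base.

    The interval is converted into the item's own device-local clock, data
    are read there, and the returned timestamps are converted back into
    ``ref_in``'s clock.  ``item`` must expose ``item_key`` and
    ``read_local(epoch_id, t0, t1) -> (data, times)``.
    """
    src = _resolve_source(graph, ref_in)
    mapping, target = graph.path_mapping(
        src, item.item_key, ClockType.DEV_LOCAL_TIME
    )
    t0_local = mapping.apply(t_i - ref_in.offset)
    t1_local = mapping.apply(t_j - ref_in.offset)
    data, times_local = item.read_local(target[1], t0_local, t1_local)
    inv = mapping.inverse()
    times_out = inv.apply(np.asarray(times_local, dtype=float)) + ref_in.offset
    return data, times_out, ref_in
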