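"""Probes and derived elements: experiment items addressable independently
of the DAQ systems that recorded them.

A *probe* is an instrument (electrode, stimulus monitor, ...) defined by the
per-epoch probe maps; it inherits its epochs — and their clocks — from the
DAQ system underneath.  A *derived element* is anything else that should go
through the same analysis pipelines: a filtered copy of a probe, a neuron's
spike times, or purely artificial data.  Derived elements either inherit the
epochs of an underlying item or carry their own stored data ("direct"
elements), kept as document blobs in the session database so derived data
stays inside the audited store.

Every element reads through the same call signature, which is what lets one
pipeline run unchanged on raw, filtered, or simulated data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import daq as daq_io
from .docdb import new_document
from .errors import ConflictError, NDIError, ValidationError
from .query import q_and, q_exact, q_isa, q_number
from .timesync import ClockType


@dataclass
class ElementEpoch:
    epoch_id: str
    clocktypes: list
    t0: float = 0.0
    t1: float = 0.0
    daq_name: str | None = None
    document_id: str | None = None  # epoch doc holding stored data (direct)


@dataclass
class Element:
    """An addressable experiment item (probe or derived element)."""

    session: object
    name: str
    reference: int
    type: str
    subject: str
    element_kind: str = "timeseries"  # or "events"
    direct: bool = False
    underlying: "Element | str | None" = None
    channels: tuple = ()
    daq_name: str | None = None
    document_id: str | None = None
    epochs: list = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.name}|{self.reference}|{self.type}"

    @property
    def item_key(self) -> str:
        return f"element:{self.key}"

    def underlying_key(self) -> str | None:
        if isinstance(self.underlying, Element):
            return self.underlying.item_key
        if self.daq_name:
            return f"daq:{self.daq_name}"
        return None

    def epoch(self, epoch_id: str) -> ElementEpoch:
        for ep in self.epochs:
            if ep.epoch_id == epoch_id:
                return ep
        raise NDIError(f"element {self.key}: no epoch {epoch_id}")

    # -- reading -----------------------------------------------------------
    def read_local(self, epoch_id: str, t0: float, t1: float):
        """Read this element's data on its own device-local clock.

        Timeseries elements return (samples, times); event elements return
        (values, event_times) restricted to [t0, t1).
        """
        ep = self.epoch(epoch_id)
        if self.direct:
            return self._read_stored(ep, t0, t1)
        if self.daq_name is not None:
            system = self.session.get_daq(self.daq_name)
            if self.element_kind == "timeseries":
                return system.read_channels(
                    self.session.root, epoch_id, list(self.channels), t0, t1
                )
            events = system.read_events(
                self.session.root, epoch_id, self.channels[0]
            )
            times = np.array([t for t, _ in events])
            mask = (times >= t0) & (times < t1)
            values = [v for (t, v), m in zip(events, mask) if m]
            return values, times[mask]
        if isinstance(self.underlying, Element):
            return self.underlying.read_local(epoch_id, t0, t1)
        raise NDIError(f"element {self.key} has no data source")

    def _read_stored(self, ep: ElementEpoch, t0: float, t1: float):
        blob = self.session.database.get_blob(ep.document_id)
        arrays = np.load(io.BytesIO(blob))
        times = arrays["times"]
        mask = (times >= t0) & (times < t1)
        if self.element_kind == "timeseries":
            return arrays["samples"][mask], times[mask]
        return times[mask], times[mask]


# ---------------------------------------------------------------------------
# discovery


def _subject_doc(session, local_id: str) -> str:
    store = session.database
    hits = store.find(q_and(q_isa("subject"), q_exact("local_id", local_id)))
    if hits:
        return hits[0]
    doc = new_document("subject", session.id, {"local_id": local_id,
                                               "description": ""})
    return store.add(doc)


def _element_doc(session, name, reference, etype, kind, direct,
                 subject_id, underlying_doc=None) -> str:
    store = session.database
    hits = _find_element_docs(session, name, reference, etype)
    if hits:
        return hits[0]
    deps = [{"name": "subject_id", "value": subject_id}]
    if underlying_doc:
        deps.append({"name": "underlying_id", "value": underlying_doc})
    doc = new_document(
        "element", session.id,
        {"name": name, "reference": int(reference), "type": etype,
         "direct": int(direct), "element_kind": kind},
        depends_on=deps,
    )
    return store.add(doc)


def _find_element_docs(session, name, reference, etype):
    return session.database.find(
        q_and(
            q_isa("element"),
            q_exact("name", name),
            q_number("reference", int(reference)),
            q_exact("type", etype),
        )
    )


def discover_probes(session) -> list[Element]:
    """Union of distinct probe-map rows across all epochs of all DAQs.

    Each probe lists the epochs where it appears.  A (name, reference) seen
    with conflicting types or subjects raises a validation error.
    """
    daq_names = [d.name for d in session.daq_systems()]
    probes: dict[tuple, Element] = {}
    for system in session.daq_systems():
        for entry in system.epochs(session.root):
            t0, t1 = system.epoch_interval(session.root, entry.epoch_id)
            for row in daq_io.load_probemap(entry, daq_names):
                if row.daq_name != system.name:
                    continue
                ident = (row.name, row.reference)
                kind = "events" if row.channels[0].startswith("e") \
                    else "timeseries"
                if ident in probes:
                    probe = probes[ident]
                    if probe.type != row.type:
                        raise ValidationError(
                            f"probe {row.name}/{row.reference} has "
                            f"conflicting types {probe.type!r} vs {row.type!r}"
                        )
                    if probe.subject != row.subject:
                        raise ValidationError(
                            f"probe {row.name}/{row.reference} has "
                            f"conflicting subjects"
                        )
                else:
                    probes[ident] = Element(
                        session=session, name=row.name,
                        reference=row.reference, type=row.type,
                        subject=row.subject, element_kind=kind,
                        channels=row.channels, daq_name=row.daq_name,
                    )
                probes[ident].epochs.append(
                    ElementEpoch(
                        epoch_id=entry.epoch_id,
                        clocktypes=list(entry.clocktypes),
                        t0=t0, t1=t1, daq_name=system.name,
                    )
                )
    result = []
    for ident in sorted(probes):
        probe = probes[ident]
        subject_id = _subject_doc(session, probe.subject)
        probe.document_id = _element_doc(
            session, probe.name, probe.reference, probe.type,
            probe.element_kind, direct=False, subject_id=subject_id,
        )
        result.append(probe)
    return result


# ---------------------------------------------------------------------------
# derived elements


def create_derived_element(session, name: str, reference: int, etype: str,
                           underlying: Element | None = None,
                           epochs_data: dict | None = None,
                           element_kind: str = "timeseries",
                           subject: str | None = None) -> Element:
    """Register a derived element (and its stored epochs, when direct).

    ``epochs_data`` maps epoch_id -> dict with ``times`` (and ``samples`` for
    timeseries kinds, plus optional ``t0``/``t1``/``sample_rate``).  When
    omitted, the element inherits the epochs of ``underlying``.  Elements
    with no underlying item must be direct (artificial/simulated data).
    """
    if underlying is None and epochs_data is None:
        raise NDIError(
            "a derived element needs an underlying item or its own data"
        )
    if _find_element_docs(session, name, reference, etype):
        raise ConflictError(
            f"element {name}|{reference}|{etype} already exists"
        )
    direct = epochs_data is not None
    subject = subject or (underlying.subject if underlying else "artificial")
    subject_id = _subject_doc(session, subject)
    doc_id = _element_doc(
        session, name, reference, etype, element_kind, direct, subject_id,
        underlying_doc=underlying.document_id if underlying else None,
    )
    element = Element(
        session=session, name=name, reference=int(reference), type=etype,
        subject=subject, element_kind=element_kind, direct=direct,
        underlying=underlying, document_id=doc_id,
    )
    if direct:
        for epoch_id in sorted(epochs_data):
            payload = epochs_data[epoch_id]
            times = np.asarray(payload["times"], dtype=float)
            buf = io.BytesIO()
            arrays = {"times": times}
            if element_kind == "timeseries":
                arrays["samples"] = np.asarray(payload["samples"], dtype=float)
            np.savez(buf, **arrays)
            clocktypes, t0, t1 = _epoch_clockinfo(underlying, epoch_id,
                                                  payload, times)
            epoch_doc = new_document(
                "epoch", session.id,
                {
                    "epoch_id": epoch_id,
                    "clocktypes": [str(c.value) for c in clocktypes],
                    "t0": t0, "t1": t1, "kind": element_kind,
                    "sample_rate": float(payload.get("sample_rate", 0.0)),
                },
                depends_on=[{"name": "element_id", "value": doc_id}],
            )
            ep_doc_id = session.database.add(epoch_doc, blob=buf.getvalue())
            element.epochs.append(
                ElementEpoch(
                    epoch_id=epoch_id, clocktypes=list(clocktypes),
                    t0=t0, t1=t1, document_id=ep_doc_id,
                )
            )
    elif underlying is not None:
        for ep in underlying.epochs:
            element.epochs.append(
                ElementEpoch(
                    epoch_id=ep.epoch_id, clocktypes=list(ep.clocktypes),
                    t0=ep.t0, t1=ep.t1, daq_name=ep.daq_name,
                )
            )
    return element


def _epoch_clockinfo(underlying, epoch_id, payload, times):
    """Clock types and interval for a stored epoch.

    Inherits the underlying item's epoch clock when available; a direct
    element with no underlying item has no convertible clock unless one is
    stated explicitly.
    """
    if underlying is not None:
        ep = underlying.epoch(epoch_id)
        return list(ep.clocktypes), ep.t0, ep.t1
    t0 = float(payload.get("t0", times[0] if len(times) else 0.0))
    t1 = float(payload.get("t1", times[-1] + 1e-9 if len(times) else 0.0))
    clock = payload.get("clocktype", ClockType.NO_TIME)
    return [clock], t0, t1
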