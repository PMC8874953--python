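"""Experiment sessions: the registry tying raw data, DAQ systems, and the
document database together.

A session lives at a root directory containing the raw data.  All session
state — the session identifier, one JSON config per DAQ system, persisted
epoch-id maps, and the document store — lives in plain files under a hidden
``.ndi`` directory at the root, so a session is inspectable and diff-able
and reopening it is idempotent.
"""

from __future__ import annotations

import json
from pathlib import Path

from .daq import DaqSystem
from .docdb import DocumentStore
from .errors import ConflictError, SessionMetadataError
from .ids import new_identifier

DOTDIR = ".ndi"


class Session:
    def __init__(self, root, reference: str | None = None):
        self.root = Path(root)
        if not self.root.is_dir():
            raise OSError(f"session root {self.root} does not exist")
        self.dotdir = self.root / DOTDIR
        meta_path = self.dotdir / "session.json"
        if meta_path.exists():
            try:
                meta = json.loads(meta_path.read_text())
                self.id = meta["id"]
                self.reference = meta["reference"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise SessionMetadataError(
                    f"session metadata invalid at {meta_path}: {exc}"
                ) from exc
        else:
            (self.dotdir / "daq").mkdir(parents=True, exist_ok=True)
            self.id = new_identifier()
            self.reference = reference if reference is not None else ""
            meta_path.write_text(
                json.dumps({"id": self.id, "reference": self.reference},
                           indent=1)
            )
        (self.dotdir / "daq").mkdir(parents=True, exist_ok=True)
        self._database: DocumentStore | None = None

    # -- database -----------------------------------------------------------
    @property
    def database(self) -> DocumentStore:
        if self._database is None:
            self._database = DocumentStore(self.dotdir / "db")
        return self._database

    # -- DAQ registry ---------------------------------------------------------
    def _daq_path(self, name: str) -> Path:
        return self.dotdir / "daq" / f"{name}.json"

    def add_daq_system(self, daq: DaqSystem) -> None:
        path = self._daq_path(daq.name)
        if path.exists():
            raise ConflictError(
                f"DAQ system {daq.name!r} already exists in this session"
            )
        path.write_text(json.dumps(daq.to_config(), indent=1, sort_keys=True))

    def daq_systems(self) -> list[DaqSystem]:
        systems = []
        for path in sorted((self.dotdir / "daq").glob("*.json")):
            systems.append(DaqSystem.from_config(json.loads(path.read_text())))
        return systems

    def get_daq(self, name: str) -> DaqSystem:
        path = self._daq_path(name)
        if not path.exists():
            raise KeyError(f"no DAQ system {name!r} in session")
        return DaqSystem.from_config(json.loads(path.read_text()))

    def syncrules(self) -> list[dict]:
        """All sync-rule configs declared across the session's DAQ configs."""
        rules = []
        for daq in self.daq_systems():
            rules.extend(daq.syncrules)
        return rules

    # -- convenience ----------------------------------------------------------
    def epochs(self, daq_name: str):
        return self.get_daq(daq_name).epochs(self.root)

    def __repr__(self):  # pragma: no cover
        return f"Session({self.reference!r}, id={self.id}, root={self.root})"


def create_session(reference: str, root_path) -> Session:
    """Create a session at ``root_path`` (or reopen the one already there)."""
    return Session(root_path, reference=reference)


def open_session(root_path) -> Session:
    """Open an existing session (creates metadata if absent)."""
    return Session(root_path)
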