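"""DAQ systems: file navigators, epoch tables, and toy-format readers.

A DAQ system couples a *file navigator* — a parameterized rule for grouping
raw files on disk into recording epochs — with a *reader* that knows the
file format.  Epochs are numbered 1..N in deterministic (lexicographic)
order and each receives an immutable identifier, persisted in a hidden
id-map so that re-scans, added epochs, or deleted epochs never change an
existing epoch's id.

Channel namespace: analog inputs ``ai1..aiN``, digital inputs ``di1..diN``,
event/marker channels ``e1..``.  All times are device-local seconds; an
epoch covers the half-open interval [t0, t1) and sample k lies at
``t0 + k/rate``.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import toyformats
from .errors import (
    NDIError,
    NoSuchChannelError,
    UnsupportedChannelError,
    ValidationError,
)
from .ids import new_identifier
from .timesync import ClockType

NAVIGATOR_KINDS = ("flat", "epochdir")
READER_KINDS = ("mfdaq_toybin", "stim_toystim")


@dataclass(frozen=True)
class FileNavigator:
    """Organization rule for locating each epoch's files.

    ``flat``: every file directly under the session root that matches all
    ``file_parameters`` regexes is its own epoch.  ``epochdir``: every
    immediate subdirectory containing at least one match per regex is an
    epoch (a subdirectory missing any required file type is not a valid
    epoch and is skipped).
    """

    kind: str
    file_parameters: tuple

    def __post_init__(self):
        if self.kind not in NAVIGATOR_KINDS:
            raise ValueError(f"unknown navigator kind {self.kind!r}")
        object.__setattr__(self, "file_parameters", tuple(self.file_parameters))


@dataclass
class EpochTableEntry:
    epoch_number: int
    epoch_id: str
    files: list
    clocktypes: list
    daq_name: str


@dataclass(frozen=True)
class ProbeMapRow:
    name: str
    reference: int
    type: str
    devicestring: str
    subject: str
    daq_name: str = ""
    channels: tuple = ()


@dataclass
class DaqSystem:
    """A named recording entity: navigator + reader (+ sync-rule configs)."""

    name: str
    navigator: FileNavigator
    reader: str
    syncrules: list = field(default_factory=list)

    def __post_init__(self):
        if ":" in self.name or not self.name:
            raise ValueError(
                f"DAQ name {self.name!r} invalid: must be a nonempty token "
                f"without ':'"
            )
        if self.reader not in READER_KINDS:
            raise ValueError(f"unknown reader kind {self.reader!r}")

    # -- config round-trip -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "name": self.name,
            "reader": self.reader,
            "navigator": {
                "kind": self.navigator.kind,
                "file_parameters": list(self.navigator.file_parameters),
            },
            "syncrules": list(self.syncrules),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DaqSystem":
        nav = FileNavigator(
            kind=cfg["navigator"]["kind"],
            file_parameters=tuple(cfg["navigator"]["file_parameters"]),
        )
        return cls(
            name=cfg["name"],
            navigator=nav,
            reader=cfg["reader"],
            syncrules=list(cfg.get("syncrules", [])),
        )

    # -- epoch table --------------------------------------------------------
    def epochs(self, root) -> list[EpochTableEntry]:
        return navigator_epochs(self, root)

    def epoch(self, root, which) -> EpochTableEntry:
        """Look up an epoch by id (string) or 1-based number (int)."""
        entries = self.epochs(root)
        if isinstance(which, int):
            for e in entries:
                if e.epoch_number == which:
                    return e
        else:
            for e in entries:
                if e.epoch_id == which:
                    return e
        raise NDIError(f"DAQ {self.name!r}: no epoch {which!r}")

    # -- reading ------------------------------------------------------------
    def read_channels(self, root, which, channels, t_start, t_end):
        entry = self.epoch(root, which)
        return read_channels(self, entry, channels, t_start, t_end)

    def read_events(self, root, which, channel):
        entry = self.epoch(root, which)
        return read_events(self, entry, channel)

    def epoch_interval(self, root, which):
        entry = self.epoch(root, which)
        return epoch_interval(self, entry)

    def utc_anchor(self, root, which):
        entry = self.epoch(root, which)
        if self.reader != "stim_toystim":
            return None
        data = toyformats.read_toystim(_stim_file(entry))
        return data["clock"].get("utc_anchor")


# ---------------------------------------------------------------------------
# navigation


def _idmap_path(root, daq_name) -> Path:
    return Path(root) / ".ndi" / "epochids" / f"{daq_name}.json"


def _epoch_key(root, files) -> str:
    rel = sorted(str(Path(f).relative_to(root)) for f in files)
    return hashlib.sha256("\n".join(rel).encode()).hexdigest()


def _assign_epoch_ids(root, daq_name, groups):
    """Map each file group to a persistent identifier (created on first sight)."""
    path = _idmap_path(root, daq_name)
    idmap = {}
    if path.exists():
        idmap = json.loads(path.read_text())
    changed = False
    ids = []
    for files in groups:
        key = _epoch_key(root, files)
        if key not in idmap:
            idmap[key] = new_identifier()
            changed = True
        ids.append(idmap[key])
    if changed:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(idmap, indent=1, sort_keys=True))
    return ids


def navigator_epochs(daq: DaqSystem, root) -> list[EpochTableEntry]:
    """Scan ``root`` with the DAQ's navigator and return the epoch table."""
    root = Path(root)
    if not root.is_dir():
        raise OSError(f"session root {root} is not a readable directory")
    nav = daq.navigator
    patterns = [re.compile(p) for p in nav.file_parameters]
    groups: list[list[Path]] = []
    if nav.kind == "flat":
        for f in sorted(p for p in root.iterdir() if p.is_file()):
            if all(pat.search(f.name) for pat in patterns):
                groups.append([f])
    else:  # epochdir
        for d in sorted(p for p in root.iterdir() if p.is_dir()):
            if d.name.startswith("."):
                continue
            files = sorted(p for p in d.iterdir() if p.is_file())
            matched: set[Path] = set()
            valid = True
            for pat in patterns:
                hits = [f for f in files if pat.search(f.name)]
                if not hits:
                    valid = False
                    break
                matched.update(hits)
            if valid:
                groups.append(sorted(matched))
    ids = _assign_epoch_ids(root, daq.name, groups)
    entries = []
    for num, (files, eid) in enumerate(zip(groups, ids), start=1):
        entries.append(
            EpochTableEntry(
                epoch_number=num,
                epoch_id=eid,
                files=[Path(f) for f in files],
                clocktypes=_epoch_clocktypes(daq, files),
                daq_name=daq.name,
            )
        )
    return entries


def _epoch_clocktypes(daq: DaqSystem, files) -> list[ClockType]:
    cts = [ClockType.DEV_LOCAL_TIME]
    if daq.reader == "stim_toystim":
        data = toyformats.read_toystim(_stim_file_from(files))
        if data["clock"].get("utc_anchor") is not None:
            cts.append(ClockType.UTC)
    return cts


# ---------------------------------------------------------------------------
# reading


_CHAN_RE = re.compile(r"^([a-z]+)(\d+)$")


def parse_channel(name: str):
    m = _CHAN_RE.match(name)
    if not m:
        raise NoSuchChannelError(f"malformed channel name {name!r}")
    return m.group(1), int(m.group(2))


def _bin_file(entry: EpochTableEntry) -> Path:
    return _file_with_suffix(entry.files, ".toybin", entry)


def _stim_file(entry: EpochTableEntry) -> Path:
    return _file_with_suffix(entry.files, ".toystim", entry)


def _stim_file_from(files) -> Path:
    for f in files:
        if str(f).endswith(".toystim"):
            return Path(f)
    raise NDIError(f"no .toystim file among {list(map(str, files))}")


def _file_with_suffix(files, suffix, entry) -> Path:
    for f in files:
        if str(f).endswith(suffix):
            return Path(f)
    raise NDIError(
        f"epoch {entry.epoch_id} of {entry.daq_name!r} has no {suffix} file"
    )


def epoch_interval(daq: DaqSystem, entry: EpochTableEntry):
    """Device-local [t0, t1) covered by the epoch."""
    if daq.reader == "mfdaq_toybin":
        hdr = toyformats.read_toybin_header(_bin_file(entry))
        return hdr["t0"], hdr["t0"] + hdr["n_samples"] / hdr["sample_rate"]
    data = toyformats.read_toystim(_stim_file(entry))
    times = list(data["triggers"]) + [p["offset"] for p in data["presentations"]]
    return 0.0, (max(times) if times else 0.0)


def channel_list(daq: DaqSystem, entry: EpochTableEntry) -> list[str]:
    """Channels exactly as derivable from the epoch's file headers."""
    if daq.reader == "mfdaq_toybin":
        hdr = toyformats.read_toybin_header(_bin_file(entry))
        return [f"ai{i}" for i in range(1, hdr["n_analog"] + 1)] + [
            f"di{i}" for i in range(1, hdr["n_digital"] + 1)
        ]
    return ["e1", "e2", "e3"]


def read_channels(daq: DaqSystem, entry: EpochTableEntry, channels,
                  t_start: float, t_end: float):
    """Sampled data for [t_start, t_end) -> (samples (n, len(channels)), times).

    Times are device-local; the interval is clipped to the epoch and the
    result is empty when disjoint.
    """
    if daq.reader != "mfdaq_toybin":
        raise UnsupportedChannelError(
            f"reader {daq.reader!r} has no sampled channels"
        )
    if t_end < t_start:
        raise ValueError("t_start must be <= t_end")
    hdr, analog, digital = toyformats.read_toybin(_bin_file(entry))
    rate, t0 = hdr["sample_rate"], hdr["t0"]
    n = hdr["n_samples"]
    cols = []
    for ch in channels:
        prefix, num = parse_channel(ch)
        if prefix == "ai" and 1 <= num <= hdr["n_analog"]:
            cols.append(analog[:, num - 1])
        elif prefix == "di" and 1 <= num <= hdr["n_digital"]:
            cols.append(digital[:, num - 1].astype(np.float32))
        else:
            raise NoSuchChannelError(
                f"no such channel {ch!r} in epoch {entry.epoch_id}"
            )
    i0 = max(0, int(np.ceil((t_start - t0) * rate - 1e-9)))
    i1 = min(n, int(np.ceil((t_end - t0) * rate - 1e-9)))
    i1 = max(i0, i1)
    samples = (
        np.column_stack([c[i0:i1] for c in cols])
        if cols
        else np.zeros((max(0, i1 - i0), 0), dtype=np.float32)
    )
    times = t0 + np.arange(i0, i1) / rate
    return samples, times


def rising_edges(bits: np.ndarray, rate: float, t0: float) -> np.ndarray:
    """Times of 0->1 transitions in a digital sample vector."""
    bits = np.asarray(bits).astype(np.int8)
    if bits.size == 0:
        return np.zeros(0)
    edges = np.flatnonzero(np.diff(bits) == 1) + 1
    if bits[0] == 1:
        edges = np.concatenate([[0], edges])
    return t0 + edges / rate


def read_events(daq: DaqSystem, entry: EpochTableEntry, channel: str):
    """Event list [(time, value/params), ...] in device-local time, sorted.

    For the multifunction reader, a digital channel yields its rising-edge
    times.  For the stimulus reader, ``e1`` = triggers, ``e2`` = presentation
    onsets (value = params incl. stim_id), ``e3`` = presentation offsets.
    """
    prefix, num = parse_channel(channel)
    if daq.reader == "mfdaq_toybin":
        if prefix != "di":
            raise UnsupportedChannelError(
                f"channel {channel!r}: only digital channels carry events on "
                f"a multifunction reader"
            )
        hdr, _analog, digital = toyformats.read_toybin(_bin_file(entry))
        if not (1 <= num <= hdr["n_digital"]):
            raise NoSuchChannelError(f"no such channel {channel!r}")
        times = rising_edges(digital[:, num - 1], hdr["sample_rate"], hdr["t0"])
        return [(float(t), 1) for t in times]
    if daq.reader == "stim_toystim":
        if prefix != "e":
            raise UnsupportedChannelError(
                f"channel {channel!r}: stimulus reader has event channels only"
            )
        data = toyformats.read_toystim(_stim_file(entry))
        if num == 1:
            return [(float(t), 1) for t in sorted(data["triggers"])]
        if num == 2:
            pres = sorted(data["presentations"], key=lambda p: p["onset"])
            return [
                (float(p["onset"]), {"stim_id": p["stim_id"], **p["params"]})
                for p in pres
            ]
        if num == 3:
            pres = sorted(data["presentations"], key=lambda p: p["offset"])
            return [(float(p["offset"]), p["stim_id"]) for p in pres]
        raise NoSuchChannelError(f"no such channel {channel!r}")
    raise UnsupportedChannelError(f"unknown reader {daq.reader!r}")


def read_presentations(daq: DaqSystem, entry: EpochTableEntry) -> dict:
    """Raw stimulus epoch content (triggers, presentations, clock)."""
    if daq.reader != "stim_toystim":
        raise UnsupportedChannelError(
            f"reader {daq.reader!r} has no stimulus presentations"
        )
    return toyformats.read_toystim(_stim_file(entry))


# ---------------------------------------------------------------------------
# probe maps

PROBEMAP_SUFFIX = ".epochprobemap.tsv"
PROBEMAP_COLUMNS = ("name", "reference", "type", "devicestring", "subject")

_DEVSTR_RE = re.compile(r"^([^:]+):([a-z]+)([\d,\-]+)$")


def parse_devicestring(devicestring: str):
    """Expand ``daq:prefixRANGE`` (e.g. ``mydaq:ai1-3,5``) -> (daq, channels)."""
    m = _DEVSTR_RE.match(devicestring.strip())
    if not m:
        raise ValidationError(f"malformed devicestring {devicestring!r}")
    daq_name, prefix, ranges = m.groups()
    nums = []
    for part in ranges.split(","):
        if "-" in part:
            lo, hi = part.split("-", 1)
            lo, hi = int(lo), int(hi)
            if hi < lo:
                raise ValidationError(
                    f"devicestring {devicestring!r}: empty range {part!r}"
                )
            nums.extend(range(lo, hi + 1))
        elif part:
            nums.append(int(part))
    if not nums:
        raise ValidationError(f"devicestring {devicestring!r}: no channels")
    return daq_name, [f"{prefix}{n}" for n in nums]


def load_probemap(entry: EpochTableEntry, daq_names=None) -> list[ProbeMapRow]:
    """Parse the epoch's ``*.epochprobemap.tsv`` sidecar(s).

    A sidecar sits next to an epoch file and is named ``<file>.epochprobemap.tsv``.
    When ``daq_names`` is given, each row's devicestring must name one of them.
    """
    rows: list[ProbeMapRow] = []
    seen = set()
    for f in entry.files:
        sidecar = Path(str(f) + PROBEMAP_SUFFIX)
        if not sidecar.exists() or sidecar in seen:
            continue
        seen.add(sidecar)
        rows.extend(_parse_probemap_file(sidecar, daq_names))
    return rows


def _parse_probemap_file(path: Path, daq_names) -> list[ProbeMapRow]:
    rows = []
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty probe map")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != PROBEMAP_COLUMNS:
        raise ValidationError(
            f"{path}:1: bad header {header!r}, expected {PROBEMAP_COLUMNS!r}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(PROBEMAP_COLUMNS):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(PROBEMAP_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        name, reference, ptype, devstr, subject = (p.strip() for p in parts)
        try:
            ref = int(reference)
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: reference {reference!r} is not an integer"
            ) from None
        daq_name, channels = parse_devicestring(devstr)
        if daq_names is not None and daq_name not in daq_names:
            raise ValidationError(
                f"{path}:{lineno}: devicestring names unknown DAQ {daq_name!r}"
            )
        rows.append(
            ProbeMapRow(
                name=name,
                reference=ref,
                type=ptype,
                devicestring=devstr,
                subject=subject,
                daq_name=daq_name,
                channels=tuple(channels),
            )
        )
    return rows


def write_probemap(path, rows) -> None:
    """Write probe-map rows as the TSV dialect read by :func:`load_probemap`."""
    lines = ["\t".join(PROBEMAP_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [r["name"], str(r["reference"]), r["type"], r["devicestring"],
                 r["subject"]]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
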