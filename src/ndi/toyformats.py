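"""Low-level readers/writers for the two toy on-disk acquisition formats.

``.toybin`` is a little-endian binary format for multifunction-DAQ data:

* a 64-byte fixed header: magic ``TOYB``, version (uint16), sample rate
  (float64), number of analog channels (uint16), number of digital channels
  (uint16), number of frames (uint64), device-local start time t0 (float64),
  zero padding to 64 bytes;
* all analog samples as float32, channel-interleaved frames
  (frame 0 channels 1..N, frame 1 channels 1..N, ...);
* all digital channels bit-packed per frame (``ceil(n_digital/8)`` bytes per
  frame, bit k of a frame's bytes = digital channel k+1, little bit order).

``.toystim`` is UTF-8 JSON describing a stimulus/event device epoch with keys
``triggers`` (list of seconds), ``presentations`` (list of objects with
``onset``, ``offset``, ``stim_id``, ``params``) and ``clock``
(``{"type": ..., "utc_anchor": ...}``); times are device-local seconds.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

TOYBIN_MAGIC = b"TOYB"
TOYBIN_VERSION = 1
_HEADER_STRUCT = struct.Struct("<4sHHdHHQd")  # magic, version, pad, rate, na, nd, n, t0
HEADER_SIZE = 64


def write_toybin(path, analog, digital, sample_rate, t0=0.0):
    """Write one ``.toybin`` epoch file.

    ``analog`` is float-like (n_frames, n_analog); ``digital`` is bool-like
    (n_frames, n_digital).  Either may have zero channels but frame counts
    must agree.
    """
    analog = np.asarray(analog, dtype=np.float32)
    digital = np.asarray(digital, dtype=np.uint8)
    if analog.ndim != 2 or digital.ndim != 2:
        raise ValueError("analog and digital must be 2-D (frames x channels)")
    n = analog.shape[0] if analog.shape[1] else digital.shape[0]
    if analog.shape[1] and digital.shape[1] and analog.shape[0] != digital.shape[0]:
        raise ValueError("analog and digital frame counts differ")
    header = _HEADER_STRUCT.pack(
        TOYBIN_MAGIC, TOYBIN_VERSION, 0, float(sample_rate),
        analog.shape[1], digital.shape[1], n, float(t0),
    )
    header = header.ljust(HEADER_SIZE, b"\x00")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(analog.tobytes(order="C"))
        if digital.shape[1]:
            packed = np.packbits(digital, axis=1, bitorder="little")
            fh.write(packed.tobytes(order="C"))


def read_toybin_header(path) -> dict:
    with open(path, "rb") as fh:
        raw = fh.read(HEADER_SIZE)
    if len(raw) < HEADER_SIZE:
        raise ValueError(f"{path}: truncated toybin header")
    magic, version, _pad, rate, na, nd, n, t0 = _HEADER_STRUCT.unpack(
        raw[: _HEADER_STRUCT.size]
    )
    if magic != TOYBIN_MAGIC:
        raise ValueError(f"{path}: not a toybin file (bad magic {magic!r})")
    return {
        "version": version,
        "sample_rate": rate,
        "n_analog": na,
        "n_digital": nd,
        "n_samples": n,
        "t0": t0,
    }


def read_toybin(path):
    """Read a whole ``.toybin`` file -> (header, analog, digital).

    ``analog`` is float32 (n, n_analog); ``digital`` is uint8 0/1
    (n, n_digital).
    """
    hdr = read_toybin_header(path)
    n, na, nd = hdr["n_samples"], hdr["n_analog"], hdr["n_digital"]
    with open(path, "rb") as fh:
        fh.seek(HEADER_SIZE)
        analog = np.frombuffer(fh.read(4 * n * na), dtype="<f4").reshape(n, na)
        if nd:
            bpf = (nd + 7) // 8
            packed = np.frombuffer(fh.read(n * bpf), dtype=np.uint8).reshape(n, bpf)
            digital = np.unpackbits(packed, axis=1, bitorder="little")[:, :nd]
        else:
            digital = np.zeros((n, 0), dtype=np.uint8)
    return hdr, analog, digital


def write_toystim(path, triggers, presentations, clock=None):
    """Write one ``.toystim`` epoch file (JSON)."""
    payload = {
        "triggers": [float(t) for t in triggers],
        "presentations": [
            {
                "onset": float(p["onset"]),
                "offset": float(p["offset"]),
                "stim_id": int(p["stim_id"]),
                "params": dict(p.get("params", {})),
            }
            for p in presentations
        ],
        "clock": dict(clock) if clock else {"type": "dev_local_time"},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_toystim(path) -> dict:
    data = json.loads(Path(path).read_text())
    for key in ("triggers", "presentations", "clock"):
        if key not in data:
            raise ValueError(f"{path}: missing toystim key {key!r}")
    return data
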