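"""Globally unique, lexicographically sortable identifiers.

An identifier is a fixed-width hexadecimal millisecond timestamp followed by
16 random hex characters (64 random bits).  Sorting identifiers as strings
therefore sorts them by creation time for creations at least one millisecond
apart, and the random suffix makes collisions vanishingly unlikely without
any central registry.
"""

from __future__ import annotations

import os
import re
import time

_ID_RE = re.compile(r"^[0-9a-f]{12}_[0-9a-f]{16}$")


def new_identifier(timestamp_ms: int | None = None) -> str:
    """Return a fresh identifier.

    Parameters
    ----------
    timestamp_ms:
        Millisecond timestamp to embed in the prefix.  Defaults to the
        current wall-clock time; an explicit value is only useful in tests.
    """
    ms = int(time.time() * 1000) if timestamp_ms is None else int(timestamp_ms)
    if ms < 0:
        raise ValueError("timestamp must be non-negative")
    return f"{ms & 0xFFFFFFFFFFFF:012x}_{os.urandom(8).hex()}"


def is_identifier(value: str) -> bool:
    """True if ``value`` has the canonical identifier shape."""
    return isinstance(value, str) and bool(_ID_RE.match(value))
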