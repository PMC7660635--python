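"""Deterministic seed hierarchy.

A single user-facing seed fans out into named substreams (negative
balancing, CV folds, ant tours, GA operators, data generators) so that
each subsystem is independently reproducible. Derived seeds stay below
2**31 so they are valid for every consumer (numpy, scikit-learn).
"""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def derive_seed(master: int, *names: str | int) -> int:
    """Derive a reproducible child seed from a master seed and a path of names.

    Uses CRC32 over the textual path, mixed with the master seed; cheap,
    stable across platforms and Python versions (unlike ``hash``).
    """
    path = "/".join(str(n) for n in names)
    h = zlib.crc32(path.encode("utf-8"))
    return (int(master) * 2654435761 + h) % _MOD
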