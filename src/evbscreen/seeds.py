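"""Deterministic seed derivation.

Every stochastic component draws its seed as a stable hash of the master
seed plus a structural identity (variant label, replica, snapshot, window
index, ...), so rebuilding a manifest — or re-running a single task in
isolation — reproduces the exact stream.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Stable seed in [0, 2³¹) from an arbitrary tuple of identifiers."""
    h = hashlib.blake2b(digest_size=8)
    for p in parts:
        h.update(repr(p).encode())
        h.update(b"\x1f")
    return int.from_bytes(h.digest(), "big") % (2 ** 31)
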