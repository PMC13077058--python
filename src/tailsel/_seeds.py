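"""Deterministic per-component seed derivation.

A single top-level seed fixes every downstream random stream. Component seeds
are derived by stable hashing of ``(seed, component name)`` so that adding a
component never shifts the streams of existing ones.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, component: str) -> int:
    """A 31-bit seed deterministically derived from ``(master, component)``."""
    digest = hashlib.sha256(f"{int(master)}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
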