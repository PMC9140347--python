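"""Deterministic seed streams.

Every source of randomness in the pipeline draws its seed from
:func:`derive_seed`, a stable hash of (master seed, stage name, unit id).
Per-gene / per-run randomness is therefore reproducible and independent of
iteration order or parallel scheduling.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, stage_name: str, unit_id: str | int = "") -> int:
    """Collision-resistant 31-bit seed for a (stage, unit) random stream."""
    key = f"{int(master_seed)}:{stage_name}:{unit_id}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
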