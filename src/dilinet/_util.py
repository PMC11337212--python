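"""Shared helpers: deterministic seed fan-out and dataset digests."""

from __future__ import annotations

import hashlib
from collections.abc import Iterable


def endpoint_seed(master_seed: int, endpoint: str) -> int:
    """Derive a per-endpoint RNG seed from a master seed and the endpoint name.

    Stable across processes (unlike ``hash()``): uses SHA-256 of the name.
    """
    h = hashlib.sha256(endpoint.encode("utf-8")).digest()
    return (master_seed + int.from_bytes(h[:4], "big")) % (2**31 - 1)


def keyset_digest(keys: Iterable[str]) -> str:
    """Order-invariant SHA-256 digest of a set of structure keys."""
    joined = "\n".join(sorted(set(keys)))
    return hashlib.sha256(joined.encode("utf-8")).hexdigest()
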