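"""Seeding and hashing helpers shared across pipeline stages."""

from __future__ import annotations

import hashlib
from typing import Iterable

import numpy as np


def derived_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a single run seed.

    Stable across processes and Python versions (sha256, not ``hash``),
    always below 2**31 so it is safe for every RNG consumer.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derived_seed(seed, stage))


def ids_hash(ids: Iterable) -> str:
    """Order-insensitive hash of a set of subject ids.

    Used to pin the held-out test split: the hash is recorded once and
    asserted by every subsequent evaluation against that split.
    """
    joined = "\n".join(sorted(str(i) for i in ids))
    return hashlib.sha256(joined.encode()).hexdigest()[:16]


def array_hash(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]
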