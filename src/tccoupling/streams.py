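"""Counter-based random-number streams.

Every stochastic operation in the package draws from a Philox generator whose
128-bit key is derived by hashing ``(master_seed, *stream_ids)``.  Streams are
therefore independent of execution order and of each other, which is what
makes paired replay possible: a manipulation that touches only the inhibitory
population re-uses bit-identical draws for every other population because
those populations' stream ids are unchanged.

Stream ids may be integers or short strings (campaign / configuration / trial
/ population / cell labels).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "derive_seed"]


def _key(seed: int, ids: tuple) -> np.ndarray:
    h = hashlib.blake2b(digest_size=16)
    h.update(str(int(seed)).encode())
    for part in ids:
        h.update(b"\x1f")
        h.update(repr(part).encode())
    d = h.digest()
    return np.frombuffer(d, dtype=np.uint64).copy()


def stream(seed: int, *ids) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, *ids)``; stable across platforms."""
    return np.random.Generator(np.random.Philox(key=_key(seed, ids)))


def derive_seed(seed: int, *ids) -> int:
    """A 31-bit integer sub-seed derived from ``(seed, *ids)``."""
    return int(_key(seed, ids)[0] % np.uint64(2**31 - 1))
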