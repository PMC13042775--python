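"""Named, reproducible random streams.

All randomness in the package flows from one integer seed.  Substreams are
derived from the root seed plus a tuple of string/int keys, so that e.g. the
stream for ROI 7 of the simulation is identical whether the full dataset or
only that ROI is generated.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same ``(seed, *keys)`` tuple always yields the same stream, and
    distinct key tuples yield independent streams (via SeedSequence spawning
    semantics on the hashed keys).
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys])
    return np.random.default_rng(ss)
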