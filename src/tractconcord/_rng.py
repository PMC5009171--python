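"""Named random substreams.

All randomness in the package flows from a single integer seed.  Each
consumer asks for a stream by name; the name is hashed into the seed
sequence, so adding a new stream never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a generator keyed by ``(master_seed, name)``.

    Deterministic: the same pair always yields the same stream, and
    streams with different names are statistically independent.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def child_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic integer seed for a named pipeline stage."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), key])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))
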