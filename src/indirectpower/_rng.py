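"""Named, order-independent random substreams.

A root seed plus a stream name deterministically identifies a generator, so
drawing more bootstrap replicates never perturbs the MRI simulation stream and
vice versa.  Names are hashed with CRC-32 (stable across platforms and Python
hash randomization).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_id"]


def stream_id(name: str) -> int:
    """Stable 32-bit identifier for a named substream."""
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a PCG64 generator keyed by ``(seed, name)``.

    The same (seed, name) pair always yields the same stream; distinct names
    yield statistically independent streams.
    """
    seq = np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF, stream_id(name)])
    return np.random.default_rng(seq)
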