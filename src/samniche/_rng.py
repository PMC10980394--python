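"""Named, independent RNG streams derived from a single integer seed.

Every stochastic operation in the package draws from its own stream so that
stages can be re-run independently without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stream `name` under the global `seed`.

    The stream key is a CRC32 of the name, so the mapping is stable across
    sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
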