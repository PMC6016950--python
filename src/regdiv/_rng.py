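"""Seed management.

All randomness in the package flows from a single integer root seed.  Each
module draws from a named substream so that, e.g., regenerating hybrid counts
does not perturb the parental counts produced under the same root seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under root ``seed``.

    The substream is keyed by the CRC32 of the name, so the mapping is stable
    across sessions and independent of the order streams are requested in.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
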