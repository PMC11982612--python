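"""Named random substreams.

Every randomized stage of the pipeline draws from its own substream derived
from the single user seed plus a stable stage name, so changing the
resampling depth of one stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of stage names.

    The names are hashed with crc32, so the mapping is stable across runs
    and platforms. Identical (seed, names) always yields the identical
    stream.
    """
    keys = [zlib.crc32(str(n).encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def resolve_rng(rng=None, seed=None, *names: object) -> np.random.Generator:
    """Accept either an explicit Generator or a seed (+ substream names)."""
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("either rng or seed must be given")
    return substream(seed, *names)
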