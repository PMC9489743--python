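"""Deterministic seed fan-out.

One master seed drives a run; every component (scene synthesis, view
transforms, bank initialisation, negative sampling, batch shuffling)
derives its own child seed from the master plus a stable string/int key
path, so changing one component's consumption pattern never perturbs the
random streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(master: int, *keys: object) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and key path."""
    tag = "/".join(str(k) for k in keys)
    h = zlib.crc32(tag.encode("utf-8"))
    # mix with a second pass so (master, key) pairs decorrelate
    mixed = zlib.crc32(f"{master}:{h}".encode("utf-8"))
    return int((master * 2654435761 + mixed) % _MOD)


def rng_for(master: int, *keys: object) -> np.random.Generator:
    """A numpy Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *keys))
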