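"""Named random substreams derived from one master seed.

Every stage of the pipeline (generation, balancing, seed construction,
partitioning, permutations, classifier initialisation) draws from its own
substream so that changing the number of draws in one stage never perturbs
another, and a run is bit-reproducible from the single master seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    The stream is keyed by CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))


def child_seed(master_seed: int, name: str) -> int:
    """A 31-bit integer seed for the named substream (for APIs taking ints)."""
    return int(substream(master_seed, name).integers(0, 2**31 - 1))
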