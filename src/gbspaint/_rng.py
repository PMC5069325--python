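"""Seed-substream derivation.

One master seed drives a run; every stochastic step pulls a child generator
keyed by a stable string label, so adding or reordering samples/species never
perturbs the random stream any other one sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _stable_hash(label: str) -> int:
    # crc32 is stable across processes/platforms (unlike hash()).
    return zlib.crc32(label.encode("utf-8"))


def substream(master_seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    Identical (seed, labels) always yield the same stream; distinct labels
    yield streams that are independent for any practical purpose.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_stable_hash(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
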