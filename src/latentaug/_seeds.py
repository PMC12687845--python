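"""Deterministic seed cascading.

A single global seed deterministically derives per-module, per-fold seeds,
so toggling one stage (e.g. the expansion mode) never reshuffles another
(e.g. fold assignment) — experiments across modes stay paired.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(global_seed: int, *tags: int | str) -> int:
    """Stable child seed in [0, 2^31) from a global seed and context tags."""
    entropy = [int(global_seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            entropy.append(zlib.crc32(tag.encode("utf-8")))
        else:
            entropy.append(int(tag) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
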