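"""Seeding helpers.

A single user-facing seed is expanded into independent named substreams
(cohort synthesis, splitting, model fitting, ...) so that, e.g., changing
the number of evaluation repeats never perturbs cohort generation.
"""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31


def substream_seed(base_seed: int, *labels: str | int) -> int:
    """Derive a deterministic 31-bit seed for a named substream."""
    entropy = [int(base_seed) % _SEED_MOD]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode()) % _SEED_MOD)
        else:
            entropy.append(int(lab) % _SEED_MOD)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def substream_rng(base_seed: int, *labels: str | int) -> np.random.Generator:
    return np.random.default_rng(substream_seed(base_seed, *labels))
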