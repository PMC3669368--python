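"""Seed plumbing: named, independent RNG streams derived from one base seed.

All stochastic code in the package takes either an integer seed or an
already-constructed :class:`numpy.random.Generator`.  Grid runs derive one
stream per (setting, purpose) pair so that enabling or disabling one test
method never perturbs the random numbers another method sees.
"""

from __future__ import annotations

import zlib

import numpy as np

RandomState = "int | np.random.Generator | np.random.SeedSequence"


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(int(seed))


def spawn_rng(base_seed: int, *labels) -> np.random.Generator:
    """Deterministic child stream keyed by ``base_seed`` and string/int labels.

    String labels are hashed with CRC-32 so the derivation is stable across
    sessions and platforms (Python's built-in ``hash`` is salted).
    """
    entropy = [int(base_seed) & 0x7FFFFFFF]
    for label in labels:
        if isinstance(label, (int, np.integer)):
            entropy.append(int(label) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(label).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))
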