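"""Hierarchical, purpose-keyed random streams.

Common random numbers across scenario arms require that a draw depend only on
(master seed, iteration, purpose, extra keys such as year or condition index)
and never on the arm being simulated or on how many draws other purposes have
consumed.  Streams are derived from ``numpy.random.SeedSequence`` with the
purpose string hashed stably (zlib.crc32, not Python's salted ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "StreamFactory"]


def _key(purpose: str) -> int:
    return zlib.crc32(purpose.encode("utf-8"))


def stream(master_seed: int, iteration: int, purpose: str, *keys: int) -> np.random.Generator:
    """A fresh generator for (master seed, iteration, purpose, keys)."""
    entropy = (int(master_seed), int(iteration), _key(purpose), *map(int, keys))
    return np.random.default_rng(np.random.SeedSequence(entropy))


class StreamFactory:
    """Bound (master seed, iteration) pair; call with a purpose + keys."""

    def __init__(self, master_seed: int, iteration: int = 0):
        self.master_seed = int(master_seed)
        self.iteration = int(iteration)

    def __call__(self, purpose: str, *keys: int) -> np.random.Generator:
        return stream(self.master_seed, self.iteration, purpose, *keys)
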