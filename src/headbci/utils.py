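"""Seeding and small shared helpers.

All randomness in the pipeline flows from one master seed through named
substreams, so that each stage (synthesis, window sampling, balancing,
splitting, weight initialisation) is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stream name."""
    return int(np.random.SeedSequence([seed, zlib.crc32(name.encode())]).generate_state(1)[0] % (2**31))


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named substream of ``seed``.

    The same (seed, name) pair always yields an identical stream; different
    names yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))
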