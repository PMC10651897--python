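"""Seed management: one global seed split into named per-stage substreams."""

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent generator for stage ``label`` under ``seed``.

    The label is hashed with CRC32 so that stages are decoupled: changing
    the draw count in one stage never perturbs another, and any stage can
    be re-run in isolation and reproduce its output bit-for-bit.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, zlib.crc32(label.encode())]))
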