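"""Named random substreams.

Every stochastic stage draws from a substream derived from a single
top-level seed and a stable stage name, so the end-to-end pipeline is
bit-reproducible and adding draws to one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator seeded by ``(seed, crc32(name))``.

    crc32 is stable across processes and Python versions, unlike the
    built-in ``hash``.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
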