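"""Named random substreams derived from one master seed.

Every stochastic component draws from ``substream(seed, name)`` so that the
stream consumed by one stage is independent of how much randomness another
stage used: changing, say, the number of ChIP reads does not perturb the
expression counts generated under the same master seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The stream name is folded into the seed sequence via CRC32, which is
    stable across platforms and Python versions.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
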