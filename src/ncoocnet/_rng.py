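"""Named random substreams derived from one root seed.

Every stochastic stage draws from a child generator keyed by a stable
string, so adding or reordering unrelated stages never perturbs the
stream another stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` under root ``seed``.

    The child seed mixes the root seed with a CRC32 of the stage name,
    which is stable across processes and Python versions (unlike
    ``hash``).
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])
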