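"""Deterministic RNG substreams.

Every stage of the pipeline draws from its own generator, keyed by the
master seed plus a small integer path (stage code, then indices).  The
scheme is a plain ``SeedSequence([seed, *key])``, so serial and any
future parallel execution of the same config+seed produce bit-identical
results.

Stage codes used by the pipeline:

====  =================================
0     cohort simulation (templates, maps)
1     group subsampling (then subsample index)
====  =================================
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return an independent generator for ``(seed, *key)``.

    ``seed`` is folded into the non-negative 31-bit range accepted
    everywhere; the key path separates stages and iteration indices.
    """
    entropy = [int(seed) & 0x7FFFFFFF, *(int(k) for k in key)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
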