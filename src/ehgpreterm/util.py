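"""Seed-derivation helpers.

All randomness in the package flows from integer seeds through
:func:`child_seed`, so every partition, SMOTE draw and synthetic record is
reproducible from a single base seed plus a structural key path.
"""

from __future__ import annotations

import numpy as np


def child_seed(*keys: int) -> int:
    """Derive a deterministic 31-bit child seed from an integer key path."""
    ss = np.random.SeedSequence([int(k) & 0xFFFFFFFF for k in keys])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def rng_from(*keys: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(*keys))
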