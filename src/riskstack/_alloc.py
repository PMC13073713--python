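"""Largest-remainder integer allocation shared by the generator and splitter."""

from __future__ import annotations

import numpy as np


def largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer units across bins with exact shares ``shares``.

    Each bin gets ``floor(share)``; the remaining units go to the bins with
    the largest fractional remainders (ties broken by lower bin index).

    ``shares`` need not sum to ``total`` exactly, but the allocation always
    does; the floors must not already exceed ``total``.
    """
    shares = np.asarray(shares, dtype=float)
    if np.any(shares < 0):
        raise ValueError("shares must be non-negative")
    base = np.floor(shares).astype(int)
    leftover = total - int(base.sum())
    if leftover < 0:
        raise ValueError(
            f"floors sum to {base.sum()} which exceeds total {total}"
        )
    if leftover > len(shares):
        raise ValueError(
            f"cannot place {leftover} leftover units in {len(shares)} bins"
        )
    remainders = shares - base
    # stable argsort => lower index wins ties
    order = np.argsort(-remainders, kind="stable")
    base[order[:leftover]] += 1
    return base
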