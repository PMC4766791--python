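"""Small shared helpers."""

from __future__ import annotations

import math
from collections.abc import Mapping


def largest_remainder(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` integer units over keys proportionally to ``weights``.

    Uses the largest-remainder (Hamilton) method: each key receives the floor
    of its exact share, and the leftover units go to the keys with the largest
    fractional remainders. Ties on the remainder are broken by the insertion
    order of ``weights``, so the result is deterministic.

    Parameters
    ----------
    weights
        Non-negative weights; at least one must be positive.
    n
        Total units to distribute (>= 0).

    Returns
    -------
    dict mapping each key to a count; counts sum to ``n`` and each count
    differs from the exact real-valued share by strictly less than 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive total")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    shares = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(math.floor(s)) for k, s in shares.items()}
    leftover = n - sum(counts.values())
    order = {k: i for i, k in enumerate(weights)}
    by_remainder = sorted(weights, key=lambda k: (-(shares[k] - counts[k]), order[k]))
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts
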