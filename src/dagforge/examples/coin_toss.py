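"""Coin-toss sequence simulator.

The model: each sample has its own probability of heads, drawn uniformly
on [0, 1], and its own toss count, drawn uniformly on {10, ..., 20}; the
observable is the resulting H/T string. Shipped as a ready-to-run YAML
document in ``specs/coin_toss.yaml``.
"""

from __future__ import annotations

import numpy as np

from ..errors import DomainError

MIN_TOSSES = 10
MAX_TOSSES = 20


def coin_toss_sequence(p_heads: float, n_tosses: int, rng: np.random.Generator) -> str:
    """Sample a string of ``n_tosses`` i.i.d. tosses, 'H' with probability
    ``p_heads`` and 'T' otherwise.

    ``n_tosses`` must lie in [10, 20] and ``p_heads`` in [0, 1];
    out-of-range values raise :class:`DomainError`.
    """
    if not 0.0 <= p_heads <= 1.0:
        raise DomainError(f"p_heads={p_heads} outside [0, 1]")
    n_tosses = int(n_tosses)
    if not MIN_TOSSES <= n_tosses <= MAX_TOSSES:
        raise DomainError(
            f"n_tosses={n_tosses} outside [{MIN_TOSSES}, {MAX_TOSSES}]"
        )
    draws = rng.random(n_tosses) < p_heads
    return "".join("H" if hit else "T" for hit in draws)
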