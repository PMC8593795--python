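"""Independent brute-force references used to validate the implementation."""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from typing import Tuple


@lru_cache(maxsize=None)
def _hypergeom_pmf(r1: int, r2: int, c1: int) -> Tuple[Tuple[int, Fraction], ...]:
    """Exact hypergeometric pmf over the support of the (1,1) cell."""
    n = r1 + r2
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return tuple(
        (a, Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom))
        for a in range(lo, hi + 1)
    )


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration in exact rational arithmetic.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    pmf = dict(_hypergeom_pmf(r1, r2, c1))
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))
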