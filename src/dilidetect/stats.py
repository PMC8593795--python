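"""Rates, the two-sided Fisher exact test, and Ryan step-down comparisons.

The Ryan (1960) step-down procedure for proportions orders the k groups by
observed rate and tests the pair spanning r ordered positions at the
adjusted nominal level

    alpha'(r) = 2 * alpha / (k * (r - 1)),

so the extreme pair is tested at the Bonferroni-over-all-pairs level
``alpha / (k*(k-1)/2)`` and adjacent pairs at ``2*alpha/k``. Coherence is
enforced step-down: an inner pair is tested only if every enclosing pair
was significant, otherwise it is declared non-significant without a test.
With k = 2 the procedure reduces to a single Fisher test at ``alpha``.

The two-sided Fisher p-value uses the point-probability definition: the sum
of hypergeometric probabilities of all tables with the observed margins
whose point probability does not exceed the observed table's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

from scipy.stats import fisher_exact as _scipy_fisher_exact

__all__ = [
    "Rate",
    "rate",
    "round_half_up",
    "fisher_exact_two_sided",
    "PairDecision",
    "RateComparison",
    "ryan_stepdown",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (25 -> 3 at 1 digit would give 2.5, etc.)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Rate:
    numerator: int
    denominator: int
    proportion: Fraction  # exact
    percent: float  # 2 decimals, half-up

    def __str__(self) -> str:
        return f"{self.percent:.2f}%"


def rate(numerator: int, denominator: int) -> Rate:
    """Exact proportion plus the percentage rendered to 2 decimals, half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    prop = Fraction(numerator, denominator)
    # exact decimal arithmetic avoids binary-float drift at the 2nd decimal
    pct = float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return Rate(numerator, denominator, prop, pct)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Degenerate margins (an all-zero row or column) carry no information;
    p = 1 by convention with a warning.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        return 1.0
    _, p = _scipy_fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return min(float(p), 1.0)


@dataclass(frozen=True)
class PairDecision:
    group_a: str
    group_b: str
    span: int  # number of ordered groups the pair stretches over
    adjusted_alpha: float
    p_value: float | None  # None when skipped for step-down coherence
    significant: bool
    tested: bool


@dataclass(frozen=True)
class RateComparison:
    labels: Tuple[str, ...]  # ordered by observed proportion, ascending
    numerators: Tuple[int, ...]
    denominators: Tuple[int, ...]
    rates: Tuple[float, ...]  # proportions in the ordered layout
    alpha: float
    decisions: Tuple[PairDecision, ...]

    def decision(self, a: str, b: str) -> PairDecision:
        for d in self.decisions:
            if {d.group_a, d.group_b} == {a, b}:
                return d
        raise KeyError(f"no decision for pair ({a}, {b})")


def ryan_stepdown(
    groups: Dict[str, Tuple[int, int]] | Sequence[Tuple[str, int, int]],
    alpha: float = 0.05,
) -> RateComparison:
    """Ryan step-down multiple comparison of k binomial proportions.

    ``groups`` maps label -> (numerator, denominator), or is a sequence of
    (label, numerator, denominator). Every unordered pair receives a
    decision; pairs skipped for coherence carry ``p_value=None``.
    """
    if isinstance(groups, dict):
        items = [(lab, n, d) for lab, (n, d) in groups.items()]
    else:
        items = [(lab, n, d) for lab, n, d in groups]
    k = len(items)
    if k < 2:
        raise ValueError("at least 2 groups are required")
    for lab, n, d in items:
        if d <= 0 or not (0 <= n <= d):
            raise ValueError(f"invalid counts for group {lab!r}: {n}/{d}")
    items.sort(key=lambda t: (Fraction(t[1], t[2]), t[0]))
    labels = tuple(lab for lab, _, _ in items)
    nums = tuple(n for _, n, _ in items)
    dens = tuple(d for _, _, d in items)

    sig: Dict[Tuple[int, int], bool] = {}
    decisions: List[PairDecision] = []
    # widest spans first so enclosing decisions exist when needed
    for span in range(k, 1, -1):
        a_prime = 2 * alpha / (k * (span - 1))
        for i in range(0, k - span + 1):
            j = i + span - 1
            enclosing_ok = all(
                sig[(i2, j2)]
                for i2 in range(0, i + 1)
                for j2 in range(j, k)
                if (i2, j2) != (i, j)
            )
            if enclosing_ok:
                p = fisher_exact_two_sided(
                    nums[i], dens[i] - nums[i], nums[j], dens[j] - nums[j]
                )
                significant = p < a_prime
                tested = True
            else:
                p, significant, tested = None, False, False
            sig[(i, j)] = significant
            decisions.append(
                PairDecision(
                    group_a=labels[i],
                    group_b=labels[j],
                    span=span,
                    adjusted_alpha=a_prime,
                    p_value=p,
                    significant=significant,
                    tested=tested,
                )
            )
    return RateComparison(
        labels=labels,
        numerators=nums,
        denominators=dens,
        rates=tuple(n / d for n, d in zip(nums, dens)),
        alpha=alpha,
        decisions=tuple(decisions),
    )
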