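"""Sampling parameters for k'-mer indexing and HSLA search.

An HSLA (highly similar local alignment) search is governed by five numbers:

* ``l``  — minimum alignment length (bp),
* ``t``  — minimum match percentage, a fraction in (0, 1],
* ``k'`` — the indexed word length (``kprime``),
* ``k*`` — the minimum maximal-exact-match (MEM) length a true alignment of
  length ``l`` with at most ``⌊(1-t)l⌋`` errors is guaranteed to contain,
* ``w``  — the fixed sampling step: only k'-mers ending at every w-th
  position of a database sequence are stored.

Hard sampling keeps ``w ≤ w0 = k* - k' + 1`` so that every MEM of length at
least ``k*`` contains a sampled k'-mer and no alignment can be lost.  Soft
sampling uses ``w > w0``, trading possible misses for a smaller index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction


def mismatch_budget(l: int, t: float | Fraction) -> int:
    """Maximum error count ``⌊(1-t)·l⌋`` of a qualifying alignment of length l.

    Evaluated with exact rational arithmetic so threshold values such as
    t = 0.97 at l = 100 floor to exactly 3.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if not 0 < t <= 1:
        raise ValueError("t must be in (0, 1]")
    return int((1 - Fraction(t)) * l)


def compute_kstar(l: int, t: float | Fraction) -> int:
    """MEM length threshold ``k* = ⌊l / (1 + ⌊(1-t)·l⌋)⌋``.

    The worst case for a length-l alignment with E errors is evenly spaced
    errors, which still leaves an exact run of at least ``⌊l/(1+E)⌋`` bases.

    >>> compute_kstar(50, 0.96)
    16
    >>> compute_kstar(100, 0.97)
    25
    """
    return l // (1 + mismatch_budget(l, t))


def compute_w0(kstar: int, kprime: int) -> int:
    """Largest hard-sampling step ``w0 = k* - k' + 1``.

    With step w0, any window of k* consecutive positions contains at least
    one sampled k'-mer, so every MEM of length >= k* is seeded.
    """
    if kstar < kprime:
        raise ValueError(f"kstar ({kstar}) must be >= kprime ({kprime})")
    return kstar - kprime + 1


@dataclass(frozen=True)
class SamplingParams:
    """The tuple (l, t, k', k*, w) governing index construction and search."""

    l: int
    t: float
    kprime: int = 12
    kstar: int = field(default=0)
    w: int = field(default=0)

    def __post_init__(self) -> None:
        if not 0 < self.t <= 1:
            raise ValueError("t must be in (0, 1]")
        if self.kstar == 0:
            object.__setattr__(self, "kstar", compute_kstar(self.l, self.t))
        if self.w == 0:
            object.__setattr__(self, "w", self.w0)
        if not self.kprime <= self.kstar <= self.l:
            raise ValueError(
                f"need kprime <= kstar <= l, got "
                f"{self.kprime}, {self.kstar}, {self.l}"
            )
        if not 1 <= self.w < self.l:
            raise ValueError(f"need 1 <= w < l, got w={self.w}, l={self.l}")

    @property
    def w0(self) -> int:
        return compute_w0(self.kstar, self.kprime)

    @property
    def hard_sampling(self) -> bool:
        return self.w <= self.w0

    @property
    def t_fraction(self) -> Fraction:
        """The match threshold as an exact rational (for boundary-safe
        comparisons like 48/50 >= 0.96)."""
        return Fraction(self.t)

    @property
    def errors(self) -> int:
        """Error budget ``⌊(1-t)·l⌋`` for a minimum-length alignment."""
        return mismatch_budget(self.l, self.t)
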