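"""Closed-form predictors of HSLA retention under soft sampling.

Two models estimate the probability that a single short HSLA of length
``|x|`` survives sampling with step ``w``:

* **Kent's model** assumes the sampled word *is* the MEM threshold word
  (w = k' = k*): with ``T = ⌊(|x| - k* + 1)/w⌋`` guaranteed non-overlapping
  sampled words, each matching with probability ``p = t^k*``, retention is
  ``1 - (1 - p)^T``.

* The **BLAST model** keeps k' < k*: a sampled k'-mer must first match
  exactly (probability ``t^k'``) and then extend into a MEM of length at
  least k*, giving a per-window success probability ``p'``.  It also
  replaces the floor count T by the exact mixture over window phases:
  ``T_f = ⌊(|x|-k*+1)/w⌋`` with probability ``p(T_f)`` and
  ``T_c = ⌈(|x|-k*+1)/w⌉`` with probability ``1 - p(T_f)``.

Both models assume alignment positions match independently with
probability t.  The binomial exceedance probability quantifies one
weakness of that assumption: conditional on nothing, a Bin(l, 1-t)
mismatch count exceeds its mean ``(1-t)l`` — so the modeled "HSLA" would
not even qualify as one — with probability 32–43% for the typical
parameter grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, expm1, log1p

from .params import mismatch_budget

__all__ = [
    "ModelInputs",
    "kent_retention",
    "blast_seed_extension_prob",
    "window_count_distribution",
    "blast_retention",
    "mismatch_exceed_prob",
]

_COEFFICIENTS = {
    # printed closed form of the seed-extension probability
    "printed": -1,
    # the count implied by enumerating the left-extension cases 0..k*-k'-1
    "derived": 0,
    # the coefficient stated in the accompanying prose
    "in_text": 1,
}


@dataclass(frozen=True)
class ModelInputs:
    """Inputs of the retention models.

    Parameters
    ----------
    x_len : int
        Ungapped database-side alignment length |x| in bp (typically l).
    t : float
        Per-position match probability (the match threshold).
    kprime : int
        Sampled word length k'.
    kstar : int
        MEM length threshold k*.
    w : int
        Sampling step.
    """

    x_len: int
    t: float
    kprime: int
    kstar: int
    w: int

    def __post_init__(self) -> None:
        if not self.kprime <= self.kstar <= self.x_len:
            raise ValueError("need kprime <= kstar <= x_len")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 0 < self.t <= 1:
            raise ValueError("t must be in (0, 1]")


def _one_minus_pow(p: float, n: int) -> float:
    """1 - (1-p)^n, stable for tiny p and large n."""
    if p >= 1.0:
        return 1.0 if n >= 1 else 0.0
    return -expm1(n * log1p(-p))


def kent_retention(m: ModelInputs) -> float:
    """Kent's expected retention rate ``1 - (1 - t^k*)^T``.

    ``T = ⌊(|x| - k* + 1)/w⌋`` counts the sampled words guaranteed to fall
    inside the alignment; the model treats k* as the sampled word size (k'
    is ignored).  Returns 0 when T = 0, i.e. when w exceeds |x| - k* + 1.
    """
    T = (m.x_len - m.kstar + 1) // m.w
    if T <= 0:
        return 0.0
    return _one_minus_pow(m.t ** m.kstar, T)


def blast_seed_extension_prob(m: ModelInputs, coefficient: str = "printed") -> float:
    """Probability p' that a sampled k'-mer matches and extends to a MEM_k*.

    The closed form is ``c · t^k* · (1-t) + t^k*`` where the coefficient c
    counts the distinct left-extension lengths.  ``coefficient`` selects the
    reading: ``"printed"`` (k*-k'-1, the default), ``"derived"`` (k*-k'),
    or ``"in_text"`` (k*-k'+1).  The result is clamped to [0, 1]; a value
    above 1 before clamping (possible for extreme parameters) raises a
    ``RuntimeWarning`` via :mod:`warnings`.
    """
    if coefficient not in _COEFFICIENTS:
        raise ValueError(
            f"coefficient must be one of {sorted(_COEFFICIENTS)}, "
            f"got {coefficient!r}"
        )
    c = m.kstar - m.kprime + _COEFFICIENTS[coefficient]
    p = c * m.t ** m.kstar * (1 - m.t) + m.t ** m.kstar
    if p > 1.0:
        import warnings

        warnings.warn(
            f"seed-extension probability {p:.6g} exceeds 1; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        p = 1.0
    return max(0.0, p)


def window_count_distribution(
    m: ModelInputs,
) -> tuple[tuple[int, Fraction], tuple[int, Fraction]]:
    """Distribution of the number of sampled windows inside the alignment.

    Assuming the sampling phase is uniform, the count is ``T_f =
    ⌊(|x|-k*+1)/w⌋`` with probability ``(w·T_c - (|x|-k*+1))/w`` and
    ``T_c = ⌈(|x|-k*+1)/w⌉`` otherwise.  When w divides |x|-k*+1 the two
    counts coincide and all mass sits on T_c.  Returns
    ``((T_f, p_f), (T_c, p_c))`` with exact rational probabilities summing
    to 1.
    """
    span = m.x_len - m.kstar + 1
    tf = span // m.w
    tc = -(-span // m.w)
    pf = Fraction(m.w * tc - span, m.w)
    return (tf, pf), (tc, 1 - pf)


def blast_retention(m: ModelInputs, coefficient: str = "printed") -> float:
    """BLAST-model expected retention rate.

    ``E[RR_B] = 1 - p(T_f)(1-p')^{T_f} - p(T_c)(1-p')^{T_c}`` combining the
    seed-extension probability p' with the exact window-count mixture.
    """
    p = blast_seed_extension_prob(m, coefficient=coefficient)
    (tf, pf), (tc, pc) = window_count_distribution(m)
    q = 1.0 - p
    return 1.0 - float(pf) * q ** tf - float(pc) * q ** tc


def mismatch_exceed_prob(l: int, t: float | Fraction) -> float:
    """P(X > ⌊(1-t)·l⌋) for X ~ Binomial(l, 1-t), by exact summation.

    This is the probability that a sequence of l independently-matching
    positions carries *more* mismatches than the error budget of a
    qualifying alignment — the mass the independence assumption places on
    outcomes that are not HSLAs at all.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    pm = 1 - Fraction(t)
    if pm == 0:
        return 0.0
    thresh = mismatch_budget(l, t)
    cdf = Fraction(0)
    for i in range(thresh + 1):
        cdf += comb(l, i) * pm ** i * (1 - pm) ** (l - i)
    return float(1 - cdf)
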