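"""Collision-aware sizing of pseudonym namespaces.

A domain that generates random pseudonyms of length ``l`` over an alphabet of
size ``a`` has a namespace of ``k = a**l`` slots.  Each new pseudonym is drawn
uniformly; if it collides with an existing one the draw is repeated, up to
``m`` attempts.  With ``n`` pseudonyms already present, a single draw succeeds
with probability

    P_new(n) = (k - n) / k

so a draw with ``m`` attempts succeeds with

    P_attempts(n) = 1 - (n / k)**m

and filling the domain with ``q`` pseudonyms succeeds (no draw ever exhausts
its retries) with probability

    P_fill(q) = prod_{n=0}^{q-1} [1 - (n/k)**m].

Given a target success probability ``T`` the minimal capacity is the smallest
``k >= q`` with ``P_fill > T``, and the required pseudonym length is
``l = ceil(log_a k)``.

Numerics: the product is evaluated in log space.  For large ``q`` a direct
loop is replaced by the exact power-sum expansion

    log P_fill = - sum_{j>=1} S_{jm}(q-1) / (j * k**(j*m))

where ``S_p(N) = sum_{n=1}^{N} n**p`` is computed exactly with big integers
via Faulhaber's formula (Bernoulli numbers); terms fall off like
``((q-1)/k)**(j*m)`` so a handful of terms suffice in every practical regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, DomainOverfullError, ValidationError

#: threshold below which p_fill uses the direct per-term product
_DIRECT_Q_MAX = 1_000_000
#: threshold below which min_capacity compares exact rational products
_EXACT_Q_MAX = 64


@dataclass(frozen=True)
class SizingRequest:
    """Parameters of a namespace-sizing problem.

    q: maximum number of pseudonyms the domain must hold.
    m: collision retries available per draw.
    T: minimum acceptable probability of filling the domain completely.
    a: alphabet size.
    """

    q: int
    m: int
    T: float
    a: int

    def __post_init__(self):
        if self.q < 1 or self.m < 1 or self.a < 2:
            raise ValidationError("q >= 1, m >= 1 and a >= 2 required")
        if not (0.0 < self.T < 1.0):
            raise ValidationError("T must lie in (0, 1)")


@dataclass(frozen=True)
class SizingResult:
    """Minimal namespace satisfying a sizing request."""

    k: int
    l: int
    achieved_probability: float


# ---------------------------------------------------------------------------
# Exact power sums (Faulhaber)

@lru_cache(maxsize=None)
def _bernoulli(p: int) -> tuple:
    """Bernoulli numbers B_0..B_p with the B_1 = +1/2 convention."""
    b = [Fraction(1)]
    for n in range(1, p + 1):
        acc = Fraction(0)
        for j in range(n):
            acc += math.comb(n + 1, j) * b[j]
        b.append(-acc / (n + 1))
    b_plus = list(b)
    if p >= 1:
        b_plus[1] = Fraction(1, 2)
    return tuple(b_plus)


def power_sum(N: int, p: int) -> int:
    """Exact ``sum_{n=1}^{N} n**p`` for integers N >= 0, p >= 1."""
    if N <= 0:
        return 0
    bern = _bernoulli(p)
    total = Fraction(0)
    for j in range(p + 1):
        total += math.comb(p + 1, j) * bern[j] * Fraction(N) ** (p + 1 - j)
    total /= p + 1
    assert total.denominator == 1
    return int(total)


# ---------------------------------------------------------------------------
# Probabilities

def p_new(n: int, k: int) -> float:
    """Probability that a single uniform draw is unused, given n of k taken."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < 0 or n > k:
        raise DomainOverfullError(f"n={n} outside [0, k={k}]")
    return (k - n) / k


def p_attempts(n: int, k: int, m: int) -> float:
    """Probability that at least one of m attempts draws an unused slot."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < 0 or n > k:
        raise DomainOverfullError(f"n={n} outside [0, k={k}]")
    return 1.0 - (n / k) ** m


def _log_p_fill_direct(q: int, k: int, m: int) -> float:
    n = np.arange(q, dtype=np.float64)
    return float(np.log1p(-((n / k) ** m)).sum())


def _log_p_fill_powersum(q: int, k: int, m: int, max_terms: int = 80) -> float:
    """Exact-series evaluation of log P_fill; requires (q-1)/k < 1."""
    N = q - 1
    total = Fraction(0)
    kpow = 1
    for j in range(1, max_terms + 1):
        kpow *= k ** m  # k**(j*m)
        term = Fraction(power_sum(N, j * m), j * kpow)
        total += term
        if term < Fraction(1, 10 ** 18) or (total and term / total < Fraction(1, 10 ** 16)):
            return -float(total)
    # slow convergence (k barely above q): fall back to a chunked direct sum
    return _log_p_fill_direct_chunked(q, k, m)


def _log_p_fill_direct_chunked(q: int, k: int, m: int, chunk: int = 5_000_000) -> float:
    total = 0.0
    for start in range(0, q, chunk):
        n = np.arange(start, min(start + chunk, q), dtype=np.float64)
        total += float(np.log1p(-((n / k) ** m)).sum())
    return total


def p_fill_exact(q: int, k: int, m: int) -> Fraction:
    """Exact rational P_fill for small q (reference path)."""
    if q > k:
        raise CapacityError(f"q={q} exceeds capacity k={k}")
    prod = Fraction(1)
    for n in range(q):
        prod *= 1 - Fraction(n, k) ** m
    return prod


def log_p_fill(q: int, k: int, m: int, method: str = "auto") -> float:
    """Natural log of the fill-success probability."""
    if m < 1 or q < 1 or k < 1:
        raise ValidationError("q, k, m must be >= 1")
    if q > k:
        raise CapacityError(f"q={q} exceeds capacity k={k}")
    if method == "auto":
        method = "direct" if q <= _DIRECT_Q_MAX else "powersum"
    if method == "direct":
        return _log_p_fill_direct(q, k, m)
    if method == "powersum":
        return _log_p_fill_powersum(q, k, m)
    raise ValidationError(f"unknown method {method!r}")


def p_fill(q: int, k: int, m: int, method: str = "auto") -> float:
    """Probability of drawing q distinct pseudonyms from k slots, m tries each."""
    return math.exp(log_p_fill(q, k, m, method))


# ---------------------------------------------------------------------------
# Sizing

def _fill_exceeds(q: int, k: int, m: int, T: float) -> bool:
    """P_fill(q, k, m) > T, with an exact rational comparison for tiny q."""
    if k < q:
        return False
    if q <= _EXACT_Q_MAX:
        return p_fill_exact(q, k, m) > Fraction(T)
    return log_p_fill(q, k, m) > math.log(T)


def min_capacity(q: int, m: int, T: float) -> int:
    """Smallest capacity k >= q whose fill-success probability exceeds T.

    P_fill is nondecreasing in k, so an analytic first-order seed
    ``k0 = (S_m(q-1) / -ln T)**(1/m)`` brackets the answer and a binary
    search finishes the job; the conceptual scan over all k >= q is never
    materialised.
    """
    SizingRequest(q=q, m=m, T=T, a=2)  # validates q, m, T
    if q == 1:
        return 1
    # first-order underestimate of the required capacity
    s = power_sum(q - 1, m)
    k0 = max(q, int((s / -math.log(T)) ** (1.0 / m) * 0.99))
    lo, hi = q - 1, None  # lo: known-failing (k < q always fails)
    k = k0
    if _fill_exceeds(q, k, m, T):
        hi = k
        while k > q:
            k = max(q, k // 2)
            if _fill_exceeds(q, k, m, T):
                hi = k
            else:
                lo = k
                break
        else:
            lo = q - 1
    else:
        lo = k
        while True:
            k *= 2
            if _fill_exceeds(q, k, m, T):
                hi = k
                break
            lo = k
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _fill_exceeds(q, mid, m, T):
            hi = mid
        else:
            lo = mid
    return hi


def required_length(q: int, m: int, T: float, a: int) -> int:
    """Minimal pseudonym length l with P_fill(q, a**l, m) > T (l >= 1)."""
    SizingRequest(q=q, m=m, T=T, a=a)
    k = min_capacity(q, m, T)
    l = 1
    while a ** l < k:
        l += 1
    return l


def size_namespace(request: SizingRequest) -> SizingResult:
    """Full sizing: minimal capacity, derived length, achieved probability."""
    k = min_capacity(request.q, request.m, request.T)
    l = required_length(request.q, request.m, request.T, request.a)
    return SizingResult(k=k, l=l,
                        achieved_probability=p_fill(request.q, k, request.m))


def length_table(qs: Sequence[int] = tuple(10 ** e for e in range(1, 10)),
                 alphabet_sizes: Sequence[int] = (10, 36),
                 ms: Sequence[int] = (3, 5, 10),
                 T: float = 0.99999998) -> pd.DataFrame:
    """Grid of required lengths, rows = q, columns = (a, m)."""
    cols = pd.MultiIndex.from_product([alphabet_sizes, ms], names=["a", "m"])
    rows = []
    for q in qs:
        rows.append([required_length(q, m, T, a) for a in alphabet_sizes for m in ms])
    return pd.DataFrame(rows, index=pd.Index(qs, name="q"), columns=cols)


# ---------------------------------------------------------------------------
# Monte-Carlo validation

def simulate_fill(k: int, q: int, m: int, rng: np.random.Generator) -> bool:
    """Simulate filling a k-slot namespace with q draws of up to m attempts.

    Returns True iff every draw found an unused slot within its retries.
    """
    if q > k:
        raise CapacityError(f"q={q} exceeds capacity k={k}")
    used = set()
    for _ in range(q):
        for _attempt in range(m):
            slot = int(rng.integers(k))
            if slot not in used:
                used.add(slot)
                break
        else:
            return False
    return True


def estimate_fill_probability(k: int, q: int, m: int, runs: int,
                              rng: np.random.Generator) -> float:
    """Empirical fill-success frequency over repeated simulations."""
    hits = sum(simulate_fill(k, q, m, rng) for _ in range(runs))
    return hits / runs


__all__ = [
    "SizingRequest", "SizingResult", "power_sum", "p_new", "p_attempts",
    "p_fill", "p_fill_exact", "log_p_fill", "min_capacity", "required_length",
    "size_namespace", "length_table", "simulate_fill",
    "estimate_fill_probability",
]
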