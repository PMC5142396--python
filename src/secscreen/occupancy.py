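"""Closed-form occupancy statistics for random clone picking.

When a plasmid library of ``N`` distinct members is transformed into an
expression host and single colonies are picked at random, the picking process
is well approximated by sampling *with replacement* (an urn model): each pick
lands on member ``i`` independently with probability ``w_i`` (``1/N`` for an
equiprobable library).  The number of times a designated member is recovered
among ``n`` picks is then binomial, ``X ~ Binomial(n, w_i)``, and the two
quantities screening campaigns are designed around follow in closed form:

* the *multiplicity pmf* ``P(X = m) = C(n, m) w^m (1 - w)^(n - m)``, the
  probability that one designated member is hit exactly ``m`` times;
* the *coverage probability* ``P(X >= 1) = 1 - (1 - 1/N)^n``, the probability
  that a designated member is picked at least once.  For large libraries this
  depends essentially only on the oversampling factor ``k = n/N``
  (``P(X >= 1) -> 1 - e^(-k)``), which is why three- and fourfold oversampling
  are the customary design points (coverage ~0.95 and ~0.98).

The module also provides the expected *multiplicity spectrum* — how many of
the ``N`` members one expects to see exactly ``m`` times — which is what a
Monte-Carlo simulation of the campaign (see :mod:`secscreen.simulate`)
converges to under uniform weights.

Note the deliberate distinction between two similarly named quantities:
``multiplicity_pmf`` is a per-member *probability* (denominator: nothing, it
is a probability), while the *relative occurrence* reported from a sequenced
campaign is the count of members seen exactly ``m`` times divided by the
number of picks ``n`` (see :func:`secscreen.simulate.empirical_relative_occurrence`).
They are different objects and are never conflated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

__all__ = [
    "LibraryDesign",
    "PickPlan",
    "MultiplicityDistribution",
    "multiplicity_pmf",
    "coverage_probability",
    "required_picks",
    "expected_multiplicity_spectrum",
    "round_half_away",
]

_WEIGHT_TOL = 1e-9


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    This is the convention used when comparing computed values to numbers
    printed at fixed precision (0.2874 -> 0.287, 0.95073 -> 0.95, -0.5 -> -1).
    Python's built-in ``round`` uses banker's rounding and is unsuitable.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LibraryDesign:
    """A plasmid pool of ``n_members`` variants with per-member pick weights.

    Weights default to uniform (every member equally likely to be cloned and
    picked); a non-uniform vector models abundance bias after pooled cloning.
    """

    n_members: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if int(self.n_members) != self.n_members or self.n_members < 1:
            raise ValueError(f"library size must be a positive integer, got {self.n_members}")
        if self.weights is None:
            w = np.full(self.n_members, 1.0 / self.n_members)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_members,):
                raise ValueError(
                    f"weights must have length {self.n_members}, got shape {w.shape}"
                )
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            if abs(w.sum() - 1.0) > _WEIGHT_TOL:
                raise ValueError(f"weights must sum to 1 within {_WEIGHT_TOL}, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)

    @property
    def uniform(self) -> bool:
        return bool(np.allclose(self.weights, 1.0 / self.n_members, atol=_WEIGHT_TOL))


@dataclass(frozen=True)
class PickPlan:
    """How many clones a campaign picks from a library of a given size."""

    n_picks: int
    library_size: int
    target_coverage: float | None = None

    def __post_init__(self) -> None:
        if int(self.n_picks) != self.n_picks or self.n_picks < 0:
            raise ValueError(f"number of picks must be a non-negative integer, got {self.n_picks}")
        if int(self.library_size) != self.library_size or self.library_size < 1:
            raise ValueError(f"library size must be a positive integer, got {self.library_size}")
        if self.target_coverage is not None and not 0.0 <= self.target_coverage <= 1.0:
            raise ValueError("target coverage must lie in [0, 1]")

    @property
    def oversampling_factor(self) -> float:
        return self.n_picks / self.library_size


@dataclass(frozen=True)
class MultiplicityDistribution:
    """Census of a campaign: how many members were hit exactly ``m`` times.

    ``counts`` maps multiplicity ``m >= 1`` to the number of library members
    recovered exactly ``m`` times; multiplicities conserve picks,
    ``sum(m * counts[m]) == n_picks``.  ``member_counts`` optionally retains
    the per-member hit counts the census was built from.
    """

    counts: Mapping[int, int]
    n_picks: int
    member_counts: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        counts = {int(m): int(c) for m, c in self.counts.items() if c != 0}
        if any(m < 1 for m in counts):
            raise ValueError("multiplicities must be >= 1")
        if any(c < 0 for c in counts.values()):
            raise ValueError("member counts must be non-negative")
        total = sum(m * c for m, c in counts.items())
        if total != self.n_picks:
            raise ValueError(
                f"multiplicity census conserves picks: sum(m*counts[m]) = {total} "
                f"but n_picks = {self.n_picks}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def relative_occurrence(self) -> dict[int, float]:
        """``counts[m] / n_picks`` — note the denominator is picks, not members."""
        if self.n_picks == 0:
            raise ValueError("relative occurrence undefined for a campaign of zero picks")
        return {m: c / self.n_picks for m, c in sorted(self.counts.items())}


def _check_pmf_args(n: int, N: int, m: int) -> None:
    if int(N) != N or N < 1:
        raise ValueError(f"library size must be a positive integer, got {N}")
    if int(n) != n or n < 0:
        raise ValueError(f"number of picks must be a non-negative integer, got {n}")
    if int(m) != m or m < 0 or m > n:
        raise ValueError(f"multiplicity must satisfy 0 <= m <= n, got m={m}, n={n}")


def multiplicity_pmf(n: int, N: int, m: int, weight: float | None = None) -> float:
    """Probability that a designated library member is picked exactly ``m`` times.

    ``n`` picks with replacement from ``N`` members; the designated member is
    hit per pick with probability ``weight`` (default ``1/N``), so the hit
    count is Binomial(n, weight).

    >>> round_half_away(multiplicity_pmf(66, 148, 1), 3)
    0.287
    """
    _check_pmf_args(n, N, m)
    p = 1.0 / N if weight is None else float(weight)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"member weight must lie in [0, 1], got {p}")
    # math.comb is exact; powers stay well-scaled for campaign-sized n.
    return math.comb(n, m) * p**m * (1.0 - p) ** (n - m)


def coverage_probability(n: int, N: int) -> float:
    """Probability that a designated member appears at least once in ``n`` picks.

    ``P(X >= 1) = 1 - (1 - 1/N)^n`` under the urn model with replacement.
    For ``N >= 100`` this is ~``1 - e^(-n/N)``: threefold oversampling gives
    ~0.95 coverage, fourfold ~0.98.
    """
    if int(N) != N or N < 1:
        raise ValueError(f"library size must be a positive integer, got {N}")
    if int(n) != n or n < 0:
        raise ValueError(f"number of picks must be a non-negative integer, got {n}")
    return -math.expm1(n * math.log1p(-1.0 / N)) if N > 1 else (0.0 if n == 0 else 1.0)


def required_picks(target_coverage: float, N: int) -> int:
    """Smallest ``n`` with ``coverage_probability(n, N) >= target_coverage``.

    Coverage 1.0 is unreachable with replacement in finitely many picks.
    """
    if int(N) != N or N < 1:
        raise ValueError(f"library size must be a positive integer, got {N}")
    if not 0.0 <= target_coverage < 1.0:
        raise ValueError(
            f"target coverage must lie in [0, 1); {target_coverage} is unreachable "
            "when sampling with replacement"
        )
    if target_coverage == 0.0:
        return 0
    if N == 1:
        return 1
    # Closed-form start, then settle the boundary exactly.
    n = max(0, math.ceil(math.log1p(-target_coverage) / math.log1p(-1.0 / N)) - 2)
    while coverage_probability(n, N) < target_coverage:
        n += 1
    return n


def expected_multiplicity_spectrum(n: int, N: int) -> dict[int, float]:
    """Expected number of members hit exactly ``m`` times, for ``m = 0..n``.

    Valid for equiprobable libraries only: entry ``m`` is
    ``N * multiplicity_pmf(n, N, m)`` by linearity of expectation, and the
    spectrum conserves picks, ``sum(m * entry[m]) == n``.  For biased
    libraries the closed form per member no longer aggregates this way; use
    the simulator with explicit weights instead.
    """
    _check_pmf_args(n, N, 0)
    return {m: N * multiplicity_pmf(n, N, m) for m in range(n + 1)}
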