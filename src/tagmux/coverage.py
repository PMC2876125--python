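"""Exact coverage-probability model for multiplex genotyping depth.

A sample carrying ``m`` equally amplified variants (gene copy number times
ploidy over two) yields ``n`` sequences.  Under the neutral null model every
sequence is an independent draw from the ``m`` variants with equal
probability ``1/m``, so the per-variant counts are multinomial.  The quantity

    f(r, m, n) = P(every variant observed at least r times among n draws)

is the confidence that a genotype built from those ``n`` sequences is
complete when each variant must be seen ``r`` times to be validated.  From it
derive

* ``threshold_T1`` — the minimal depth ``n`` such that the probability of an
  incomplete genotype, ``1 - f``, does not exceed ``alpha`` (default 1e-3);
* ``optimal_multiplex`` — how many samples a run of a given read budget can
  carry while guaranteeing that depth per sample.

All probabilities are computed with big-integer dynamic programming and
compared as exact rationals, so threshold boundaries are never decided by
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb, floor


@dataclass(frozen=True)
class CoverageQuery:
    """A (r, m, n, alpha) query against the coverage model.

    r: minimum observations required per variant (default 3).
    m: maximal number of variants the sample can carry.
    n: number of sequences obtained for the sample.
    alpha: tolerated probability of missing a variant (default 1e-3).
    """

    r: int = 3
    m: int = 1
    n: int = 0
    alpha: float = 1e-3

    def __post_init__(self) -> None:
        _validate(self.r, self.m, self.n)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _validate(r: int, m: int, n: int | None = None) -> None:
    if r < 1:
        raise ValueError(f"r must be a positive integer, got {r}")
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    if n is not None and n < 0:
        raise ValueError(f"n must be non-negative, got {n}")


@lru_cache(maxsize=None)
def _favourable(r: int, m: int, n: int) -> int:
    """Number of the m**n equiprobable outcome sequences in which every one
    of the m categories receives at least r of the n labelled trials.

    Convolution over categories: ways[t] = #assignments of t labelled trials
    to the categories processed so far, each category taking >= r of them.
    """
    ways = [0] * (n + 1)
    ways[0] = 1
    for _ in range(m):
        nxt = [0] * (n + 1)
        for t in range(r, n + 1):
            acc = 0
            for k in range(r, t + 1):
                if ways[t - k]:
                    acc += comb(t, k) * ways[t - k]
            nxt[t] = acc
        ways = nxt
    return ways[n]


def coverage_probability_exact(r: int, m: int, n: int) -> Fraction:
    """f(r, m, n) as an exact rational."""
    _validate(r, m, n)
    if n < r * m:
        return Fraction(0)
    return Fraction(_favourable(r, m, n), m**n)


def coverage_probability(r: int, m: int, n: int) -> float:
    """Probability that each of m equiprobable variants appears at least r
    times among n multinomial draws.

    Exact up to the final float conversion (absolute error well below 1e-12).
    """
    return float(coverage_probability_exact(r, m, n))


def threshold_T1(r: int = 3, m: int = 2, alpha: float = 1e-3) -> int:
    """Minimal depth n with 1 - f(r, m, n) <= alpha.

    f is nondecreasing in n with limit 1, so a linear scan from the smallest
    feasible depth r*m terminates.  The comparison is done on exact
    rationals; alpha is taken at its exact (binary) value.
    """
    _validate(r, m)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    target = 1 - Fraction(alpha)
    n = r * m
    while coverage_probability_exact(r, m, n) < target:
        n += 1
    return n


def optimal_multiplex(
    total_reads: int,
    r: int = 3,
    m: int = 2,
    alpha: float = 1e-3,
    assignment_efficiency: float = 1.0,
) -> int:
    """Number of samples a run of `total_reads` reads can multiplex while
    guaranteeing depth T1(r, m, alpha) per sample.

    `assignment_efficiency` discounts reads lost at demultiplexing (e.g. 0.69
    for a run where 69% of reads are assigned).  Returns
    floor(total_reads * efficiency / T1).
    """
    if total_reads < 1:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    if not 0.0 < assignment_efficiency <= 1.0:
        raise ValueError(
            f"assignment_efficiency must be in (0, 1], got {assignment_efficiency}"
        )
    t1 = threshold_T1(r, m, alpha)
    usable = Fraction(str(assignment_efficiency)) * total_reads
    return floor(usable / t1)


def coverage_table(
    r_values=(1, 3, 5, 10),
    m_values=(2, 4, 6, 8),
    n_max: int = 200,
):
    """Long-format table of f(r, m, n) for plotting depth-vs-confidence
    curves. Returns a pandas DataFrame with columns r, m, n, f."""
    import pandas as pd

    rows = [
        (r, m, n, coverage_probability(r, m, n))
        for r in r_values
        for m in m_values
        for n in range(0, n_max + 1)
    ]
    return pd.DataFrame(rows, columns=["r", "m", "n", "f"])
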