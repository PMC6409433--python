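"""Coalescent branch-length weights B_i(j) for the expected site-frequency spectrum.

The expected SFS under a stepwise demography is a linear combination of the
quantities B_i(j): the probability-weighted contribution of the portion of the
genealogy with j ancestral lineages to frequency class i, in a sample of n
alleles.  Two routes are provided:

* an exact direct evaluation of the alternating sum (rational arithmetic);
  the alternating terms suffer catastrophic cancellation in double precision,
  so this route is an oracle for small n only, and
* the numerically stable Polanski–Kimmel recursion for W^n_{i,j}, with
  B_i(j) = W^n_{i,j} / (j(j-1)), which is the production path and is finite
  and accurate in double precision for n at least 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np

__all__ = [
    "BranchWeights",
    "coefficient_C",
    "branch_weight_direct",
    "branch_weights_recursive",
    "branch_weights",
]


def coefficient_C(b: int, j: int, n: int) -> float:
    """Alternating-sum coefficient C(b, j) = prod_{l in [b,n], l != j} l(l-1)/(l(l-1)-j(j-1)).

    The empty product (b = j = n) is 1.
    """
    return float(_coefficient_C_exact(b, j, n))


def _coefficient_C_exact(b: int, j: int, n: int) -> Fraction:
    if not (2 <= b <= j <= n):
        raise ValueError(f"require 2 <= b <= j <= n, got b={b}, j={j}, n={n}")
    jj = j * (j - 1)
    out = Fraction(1)
    for l in range(b, n + 1):
        if l == j:
            continue
        ll = l * (l - 1)
        out *= Fraction(ll, ll - jj)
    return out


def branch_weight_direct(i: int, j: int, n: int) -> float:
    """B_i(j) by the direct alternating sum, in exact rational arithmetic.

    B_i(j) = (1/i) * C(n-1, i)^-1 * sum_{b=2}^{j} C(n-b, i-1) C(b, j).

    Exact, hence immune to the cancellation that breaks this formula in double
    precision; intended as an oracle for n up to ~40.
    """
    if not (1 <= i <= n - 1):
        raise ValueError(f"require 1 <= i <= n-1, got i={i}, n={n}")
    if not (2 <= j <= n):
        raise ValueError(f"require 2 <= j <= n, got j={j}, n={n}")
    acc = Fraction(0)
    for b in range(2, j + 1):
        acc += comb(n - b, i - 1) * _coefficient_C_exact(b, j, n)
    return float(acc / (i * comb(n - 1, i)))


@dataclass(frozen=True)
class BranchWeights:
    """Tables W^n_{i,j} and B_i(j) for 1 <= i <= n-1, 2 <= j <= n.

    Arrays are indexed [i-1, j-2].  ``cj`` holds the coalescent rates
    binom(j, 2) for j = 2..n, matching B's column order.
    """

    n: int
    W: np.ndarray
    B: np.ndarray

    @property
    def cj(self) -> np.ndarray:
        j = np.arange(2, self.n + 1, dtype=float)
        return j * (j - 1) / 2.0

    def row_sums(self) -> np.ndarray:
        """sum_j B_i(j), which equals 1/i for every i."""
        return self.B.sum(axis=1)


def branch_weights_recursive(n: int) -> BranchWeights:
    """Build the full W and B tables by the Polanski–Kimmel recursion.

    W_{i,2} = 6/(n+1);  W_{i,3} = 30(n-2i)/((n+1)(n+2));
    W_{i,j+2} = -[(1+j)(3+2j)(n-j)] / [j(2j-1)(n+j+1)] * W_{i,j}
                + [(3+2j)(n-2i)] / [j(n+j+1)] * W_{i,j+1}.

    Numerically stable in double precision.
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    i = np.arange(1, n, dtype=float)
    W = np.zeros((n - 1, n - 1))
    W[:, 0] = 6.0 / (n + 1)
    if n >= 3:
        W[:, 1] = 30.0 * (n - 2 * i) / ((n + 1) * (n + 2))
    for j in range(2, n - 1):  # fills column for j+2, i.e. index j
        jj = float(j)  # recursion's j runs 2..n-2
        a = -(1 + jj) * (3 + 2 * jj) * (n - jj) / (jj * (2 * jj - 1) * (n + jj + 1))
        b = (3 + 2 * jj) * (n - 2 * i) / (jj * (n + jj + 1))
        W[:, j] = a * W[:, j - 2] + b * W[:, j - 1]
    jcol = np.arange(2, n + 1, dtype=float)
    B = W / (jcol * (jcol - 1))
    return BranchWeights(n=n, W=W, B=B)


@lru_cache(maxsize=32)
def branch_weights(n: int) -> BranchWeights:
    """Cached BranchWeights for sample size n (pure function of n)."""
    return branch_weights_recursive(n)
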