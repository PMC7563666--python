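"""Shared statistics: exact Fisher tests, Weir–Cockerham theta, sex-ratio chi-square.

The two-sided Fisher test uses the "method of small p-values": the p-value is
the sum of hypergeometric probabilities, over all tables with the observed
margins, that are less than or equal to the observed table's probability.
Conventions for this differ across packages (mid-p, doubling, tolerance
gates), so the tie rule here is exact: probabilities are compared as integer
numerators over the common denominator C(n, c1), and a float is produced only
at the final division.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact_2x2", "weir_cockerham_theta", "sex_ratio_test"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Rows are the two groups (e.g. females / males), columns the two alleles.
    Empty tables (all margins zero, or a zero row/column) give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer numerators of the hypergeometric pmf over denominator C(n, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = comb(n, c1)
    acc = sum(v for v in nums if v <= obs)
    return min(1.0, acc / total)


def _genotype_summary(geno: np.ndarray) -> tuple[int, float, float]:
    """(n called, alt allele frequency, observed het proportion) for a
    (n_individuals, 2) genotype slice with -1 for missing alleles."""
    called = (geno >= 0).all(axis=1)
    n = int(called.sum())
    if n == 0:
        return 0, np.nan, np.nan
    g = geno[called]
    p = g.sum() / (2.0 * n)
    h = float((g[:, 0] != g[:, 1]).mean())
    return n, p, h


def weir_cockerham_theta(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta for one biallelic site, two groups.

    Inputs are (n, 2) diploid allele arrays (0/1, -1 missing).  Returns NaN
    when fewer than one individual is called in either group or when all
    variance components vanish (monomorphic site).
    """
    n1, p1, h1 = _genotype_summary(np.asarray(geno_a))
    n2, p2, h2 = _genotype_summary(np.asarray(geno_b))
    if n1 == 0 or n2 == 0:
        return np.nan
    r = 2.0
    n_list = np.array([n1, n2], dtype=float)
    p_list = np.array([p1, p2])
    h_list = np.array([h1, h2])
    nbar = n_list.mean()
    if nbar <= 1:
        return np.nan
    nc = (r * nbar - (n_list**2).sum() / (r * nbar)) / (r - 1.0)
    pbar = (n_list * p_list).sum() / (r * nbar)
    s2 = (n_list * (p_list - pbar) ** 2).sum() / ((r - 1.0) * nbar)
    hbar = (n_list * h_list).sum() / (r * nbar)
    if nc == 0:
        return np.nan
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return np.nan
    return float(a / denom)


def sex_ratio_test(n_males: int, n_females: int) -> tuple[float, float]:
    """1-df chi-square of an observed sex ratio against 1:1, no continuity
    correction.  Returns (statistic, p)."""
    if n_males < 0 or n_females < 0:
        raise ValueError("counts must be non-negative")
    total = n_males + n_females
    if total == 0:
        raise ValueError("at least one individual required")
    expected = total / 2.0
    chi2 = (n_males - expected) ** 2 / expected + (n_females - expected) ** 2 / expected
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p
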