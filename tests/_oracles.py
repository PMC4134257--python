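"""Independent brute-force oracles used to validate the fast implementations.

Everything here is exact rational arithmetic or naive enumeration and is
deliberately written from the definitions, not from the library code.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full hypergeometric enumeration in rationals.

    Margins fixed at (a+b, c+d, a+c); sums point probabilities of every
    table whose probability does not exceed the observed one (exact
    comparison)."""
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return Fraction(1)
    denom = math.comb(total, col1)
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    probs = {
        x: Fraction(math.comb(row1, x) * math.comb(total - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs)


def hwe_exact_fraction(n_hom_minor: int, n_het: int, n_hom_major: int) -> Fraction:
    """Exact conditional HWE p-value from the Levene-Haldane pmf
    P(h | n, n_minor) = n_minor! n_major! n! 2^h / (a! h! b! (2n)!)
    with a = (n_minor-h)/2, b = (n_major-h)/2, written out in full
    factorials and rationals."""
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n - n_minor
    if n_minor == 0 or n_major == 0:
        return Fraction(1)
    const = Fraction(
        math.factorial(n_minor) * math.factorial(n_major) * math.factorial(n),
        math.factorial(2 * n),
    )
    pmf = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        aa = (n_minor - h) // 2
        bb = (n_major - h) // 2
        pmf[h] = const * Fraction(
            2**h, math.factorial(aa) * math.factorial(h) * math.factorial(bb)
        )
    obs = pmf[n_het]
    return sum(p for p in pmf.values() if p <= obs)


def bh_quadratic(pvalues: np.ndarray) -> np.ndarray:
    """Quadratic-time BH step-up: for each p_i the smallest over all j with
    p_j >= p_i of min(1, p_j * m / rank(p_j))."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos_i, i in enumerate(order):
        best = 1.0
        for pos_j in range(pos_i, m):
            j = order[pos_j]
            best = min(best, min(1.0, p[j] * m / (pos_j + 1)))
        q[i] = best
    return q


def auc_concordance(scores: np.ndarray, outcome: np.ndarray) -> float:
    """AUC as the exhaustive concordant-pair count with ties worth 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def min_p_two_stage_naive(dosage: np.ndarray, outcome: np.ndarray,
                          mono: np.ndarray, alpha1: float) -> float:
    """Straightforward re-implementation of the two-stage min-p statistic:
    python loop over SNPs, scalar Fisher calls via scipy, allele model,
    per-SNP complete cases."""
    from scipy.stats import fisher_exact as scipy_fisher

    def allele_p(d, y):
        keep = ~np.isnan(d)
        d, y = d[keep], y[keep]
        a = int(d[y == 1].sum())
        b = int(d[y == 0].sum())
        c = int((2 - d)[y == 1].sum())
        dd = int((2 - d)[y == 0].sum())
        if (a + b == 0) or (c + dd == 0) or (a + c == 0) or (b + dd == 0):
            return 1.0
        return float(scipy_fisher([[a, b], [c, dd]])[1])

    best = 1.0
    found = False
    for j in range(dosage.shape[1]):
        p1 = allele_p(dosage[mono, j], outcome[mono])
        if p1 < alpha1:
            found = True
            best = min(best, allele_p(dosage[:, j], outcome))
    return best if found else 1.0
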