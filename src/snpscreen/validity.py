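"""Bernoulli occurrence-probability check on the permutation count.

If an adjusted p-value of k/n was produced by n permutations, the
probability of seeing exactly k exceedances under a trial probability
p_B (for instance the significance level 0.05) is the binomial point
probability C(n, k) p_B^k (1 - p_B)^(n-k).  Values this small underflow
double precision in naive form, so everything is computed in log space
via log-gamma and reported both as log10 and, when representable, as a
linear value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln


@dataclass
class BernoulliCheck:
    n: int
    k: int
    p_B: float
    log10_probability: float
    probability: float  # may be 0.0 when the linear value underflows

    def __str__(self) -> str:
        mantissa, exponent = self.mantissa_exponent()
        return (f"occurrence probability of k={self.k} in n={self.n} trials at "
                f"p_B={self.p_B}: {mantissa:.2f}x10^{exponent} "
                f"(log10 = {self.log10_probability:.4f})")

    def mantissa_exponent(self) -> tuple[float, int]:
        """Render as mantissa x 10^exponent with mantissa in [1, 10)."""
        e = math.floor(self.log10_probability)
        m = 10.0 ** (self.log10_probability - e)
        if round(m, 10) >= 10.0:  # guard the boundary after rounding
            m /= 10.0
            e += 1
        return m, e


def occurrence_probability(n: int, k: int, p_B: float) -> BernoulliCheck:
    """Binomial point probability C(n,k) p_B^k (1-p_B)^(n-k), in log space."""
    if not (isinstance(n, int) and isinstance(k, int)) or not 0 <= k <= n:
        raise ValueError("need integers 0 <= k <= n")
    if not 0.0 < p_B < 1.0:
        raise ValueError("p_B must lie strictly between 0 and 1")
    log_p = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
             + k * math.log(p_B) + (n - k) * math.log1p(-p_B))
    log10_p = float(log_p / math.log(10.0))
    linear = 10.0 ** log10_p if log10_p > -300 else 0.0
    return BernoulliCheck(n, k, p_B, log10_p, linear)
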