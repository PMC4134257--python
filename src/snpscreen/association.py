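"""Genetic-model contingency tables, Fisher's exact test, odds ratios,
and tied-rank Spearman covariate scans.

The two-sided Fisher p-value follows the probability-ordering (minimum
likelihood) rule: with all margins fixed, it sums the hypergeometric
point probabilities of every table no more probable than the observed
one, with a relative tie tolerance of 1e-7.  A small cache keyed by the
table margins makes the permutation replay cheap: under label shuffling
only the "events" margin and the observed cell move, so each distinct
margin triple is enumerated once and thereafter costs a lookup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from snpscreen.core_data import CohortTable

logger = logging.getLogger("snpscreen")

GENETIC_MODELS = ("allele", "dominant", "recessive")

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = events with the minor-bearing unit, b = non-events with it,
    c = events with the major unit, d = non-events with the major unit.

    Units are chromosomes for the allele model (each patient contributes
    two) and patients for the dominant / recessive models.
    """

    a: int
    b: int
    c: int
    d: int
    model: str = "allele"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {self.model!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    snp_id: str
    model: str
    table: ContingencyTable2x2
    p_fisher: float
    odds_ratio: float
    ci95: tuple[float, float]


@dataclass
class CovariateAssociation:
    name: str
    rho: float
    p: float
    n: int


def build_contingency(dosages: np.ndarray, outcome: np.ndarray,
                      model: str = "allele") -> ContingencyTable2x2:
    """2x2 table for one SNP under one genetic model.

    allele     -- chromosome counting: each patient contributes 2 units,
                  of which ``dosage`` carry the minor allele;
    dominant   -- patient is minor-bearing iff dosage >= 1;
    recessive  -- patient is minor-bearing iff dosage == 2.
    Missing dosages must be filtered out beforehand.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if d.shape != y.shape:
        raise ValueError("dosage / outcome length mismatch")
    if d.size == 0:
        raise ValueError("empty input")
    if np.isnan(d).any():
        raise ValueError("missing dosages must be removed before table construction")
    if model == "allele":
        minor_units = d
        unit_total = np.full_like(d, 2.0)
    elif model == "dominant":
        minor_units = (d >= 1).astype(float)
        unit_total = np.ones_like(d)
    elif model == "recessive":
        minor_units = (d == 2).astype(float)
        unit_total = np.ones_like(d)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    a = float(minor_units[y == 1].sum())
    b = float(minor_units[y == 0].sum())
    c = float((unit_total - minor_units)[y == 1].sum())
    dd = float((unit_total - minor_units)[y == 0].sum())
    return ContingencyTable2x2(int(a), int(b), int(c), int(dd), model)


def _fisher_p_vector(total: int, row1: int, col1: int) -> tuple[int, np.ndarray]:
    """Two-sided p for every admissible value of cell ``a`` at fixed margins.

    Returns (support_low, p) with p[a - support_low] the p-value for
    observed cell a.  Degenerate margins give a vector of ones.
    """
    if row1 <= 0 or col1 <= 0 or row1 >= total or col1 >= total:
        lo = max(0, row1 + col1 - total)
        hi = min(row1, col1)
        return lo, np.ones(hi - lo + 1)
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1) - gammaln(xs + 1) - gammaln(row1 - xs + 1)
        + gammaln(total - row1 + 1) - gammaln(col1 - xs + 1)
        - gammaln(total - row1 - col1 + xs + 1)
        - (gammaln(total + 1) - gammaln(col1 + 1) - gammaln(total - col1 + 1))
    )
    pmf = np.exp(logpmf)
    order = np.argsort(logpmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each observed table, p = mass of tables with pmf <= pmf_obs*(1+rtol)
    thresh = logpmf + math.log1p(_TIE_RTOL)
    pos = np.searchsorted(logpmf[order], thresh, side="right")
    p = np.minimum(csum[pos - 1], 1.0)
    return lo, p


class FisherCache:
    """Memoized two-sided Fisher p-values keyed by table margins."""

    def __init__(self) -> None:
        self._cache: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}

    def pvalue(self, total: int, row1: int, col1: int, a: int) -> float:
        key = (total, row1, col1)
        entry = self._cache.get(key)
        if entry is None:
            entry = _fisher_p_vector(total, row1, col1)
            self._cache[key] = entry
        lo, vec = entry
        return float(vec[a - lo])


_module_cache = FisherCache()


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the probability-ordering rule.

    Any zero row or column margin makes the table degenerate and the
    p-value 1.0 by convention.
    """
    return _module_cache.pvalue(table.total, table.a + table.b,
                                table.a + table.c, table.a)


def odds_ratio_ci(table: ContingencyTable2x2,
                  haldane: bool = True) -> tuple[float, tuple[float, float]]:
    """OR = a*d / (b*c) with a 95% Woolf (log-OR normal) interval.

    With ``haldane`` (default) a zero cell triggers the Haldane-Anscombe
    correction: 0.5 is added to every cell before both OR and CI.
    Without it, a zero cell yields OR 0 or +inf with a (nan, nan) CI.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0.0:
        if not haldane:
            orr = 0.0 if (a == 0 or d == 0) else math.inf
            if (a == 0 or d == 0) and (b == 0 or c == 0):
                orr = math.nan  # 0/0: undefined
            return orr, (math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - 1.96 * se)
    hi = math.exp(math.log(orr) + 1.96 * se)
    return orr, (lo, hi)


def spearman_tied(x, y) -> tuple[float, float]:
    """Tied-rank (midrank) Spearman correlation with a two-sided t-test p.

    Pairs with a missing value in either vector are dropped.  A constant
    vector leaves rho undefined (NaN, logged); |rho| = 1 returns p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("spearman_tied: constant vector, correlation undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-13:  # perfect monotone association, up to rounding
        return float(np.sign(rho)), 0.0
    return float(rho), float(p)


def covariate_scan(cohort: CohortTable, dataset: str = "second") -> pd.DataFrame:
    """Spearman scan of every covariate against the binary endpoint.

    ``dataset`` selects the monotherapy subset ("first") or the full
    cohort ("second").  Covariates constant within the chosen dataset are
    reported NA, matching how a concomitant drug absent under monotherapy
    cannot be scored there.
    """
    if dataset not in ("first", "second"):
        raise ValueError("dataset must be 'first' or 'second'")
    sub = cohort.monotherapy_subset() if dataset == "first" else cohort
    rows = []
    for name in sub.covariates.columns:
        x = pd.to_numeric(sub.covariates[name], errors="coerce").to_numpy(dtype=float)
        keep = ~np.isnan(x)
        n_used = int(keep.sum())
        if n_used < 3 or np.all(x[keep] == x[keep][0]):
            rows.append(CovariateAssociation(name, math.nan, math.nan, n_used))
            continue
        rho, p = spearman_tied(x, sub.outcome.astype(float))
        rows.append(CovariateAssociation(name, rho, p, n_used))
    return pd.DataFrame(
        [{"covariate": r.name, "rho": r.rho, "p": r.p, "n": r.n} for r in rows]
    )


def test_snp(dosages: np.ndarray, outcome: np.ndarray, snp_id: str,
             model: str = "allele", haldane: bool = True) -> AssociationResult:
    """Complete-case Fisher test of one SNP: drop missing calls, build the
    model table, test, and attach OR with its 95% CI."""
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(outcome, dtype=int)
    keep = ~np.isnan(d)
    table = build_contingency(d[keep], y[keep], model)
    p = fisher_exact_two_sided(table)
    orr, ci = odds_ratio_ci(table, haldane=haldane)
    return AssociationResult(snp_id, model, table, p, orr, ci)
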