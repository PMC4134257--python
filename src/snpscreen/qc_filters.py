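"""Per-SNP quality control: exact Hardy-Weinberg test and minor allele frequency.

The HWE test is the exact conditional test: given the diploid sample size n
and the minor-allele count, the heterozygote count follows the
Levene-Haldane distribution; the two-sided p-value sums the probabilities
of all heterozygote counts whose conditional probability does not exceed
that of the observed count.  The enumeration is carried out in exact
integer arithmetic (the sample sizes involved are small), so there are no
floating-point ties to adjudicate; no mid-p correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from snpscreen.core_data import GenotypeMatrix

logger = logging.getLogger("snpscreen")


@dataclass
class SnpQcRecord:
    snp_id: str
    genotype_counts: tuple[int, int, int]  # (hom minor, het, hom major)
    maf: float
    hwe_p: float
    passed: bool


def minor_allele_frequency(counts: tuple[int, int, int]) -> float:
    """MAF from (hom-minor, het, hom-major) genotype counts.

    Orientation is fixed upstream, so the result lies in [0, 0.5] whenever
    the input is genuinely minor-oriented; the formula itself is just
    allele counting.
    """
    n_mm, n_het, n_MM = counts
    n_total = n_mm + n_het + n_MM
    if n_total < 1:
        raise ValueError("MAF undefined for an all-missing SNP")
    return (2 * n_mm + n_het) / (2 * n_total)


def _levene_haldane_weights(n: int, n_minor: int) -> dict[int, int]:
    """Unnormalized integer weights of P(n_het | n, n_minor).

    W(h) = n! * 2**h / (((n_minor-h)/2)! * h! * ((n_major-h)/2)!); the
    common factor n_minor! n_major! / (2n)! cancels in the ratio.
    """
    n_major = 2 * n - n_minor
    lo = n_minor % 2
    hi = min(n_minor, n_major)
    fact_n = math.factorial(n)
    weights: dict[int, int] = {}
    for h in range(lo, hi + 1, 2):
        a = (n_minor - h) // 2
        b = (n_major - h) // 2
        weights[h] = fact_n * 2**h // (math.factorial(a) * math.factorial(h) * math.factorial(b))
    return weights


_EXACT_N_LIMIT = 500  # big-integer enumeration up to here, log-space beyond


def _hwe_p_logspace(n: int, n_minor: int, n_het: int) -> float:
    """Probability-ordering HWE p via vectorized log-gamma weights; used
    for sample sizes where exact integer factorials get expensive."""
    from scipy.special import gammaln

    n_major = 2 * n - n_minor
    hs = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    a = (n_minor - hs) // 2
    b = (n_major - hs) // 2
    logw = (gammaln(n + 1) + hs * math.log(2.0)
            - gammaln(a + 1) - gammaln(hs + 1) - gammaln(b + 1))
    logw -= logw.max()
    w = np.exp(logw)
    obs = logw[np.searchsorted(hs, n_het)]
    keep = logw <= obs + 1e-12
    return float(min(1.0, w[keep].sum() / w.sum()))


def hwe_exact_p(counts: tuple[int, int, int]) -> float:
    """Two-sided exact Hardy-Weinberg p-value by probability ordering.

    Monomorphic SNPs return 1.0.  At cohort-scale sample sizes the
    enumeration runs in exact integer arithmetic, so ties in the
    conditional probability are decided exactly; very large samples
    switch to an equivalent log-space evaluation.
    """
    n_mm, n_het, n_MM = counts
    if min(n_mm, n_het, n_MM) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_mm + n_het + n_MM
    if n < 1:
        raise ValueError("HWE undefined for an all-missing SNP")
    n_minor = 2 * n_mm + n_het
    n_major = 2 * n_MM + n_het
    if n_minor == 0 or n_major == 0:
        return 1.0
    if n > _EXACT_N_LIMIT:
        return _hwe_p_logspace(n, n_minor, n_het)
    weights = _levene_haldane_weights(n, n_minor)
    w_obs = weights[n_het]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def snp_qc_record(
    snp_id: str,
    dosages: np.ndarray,
    hwe_threshold: float = 0.2,
    maf_threshold: float = 0.05,
) -> SnpQcRecord:
    """QC one SNP from its per-patient dosage column (NaN = missing call)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    counts = (int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    if len(d) == 0:
        logger.info("QC: SNP %s has no called genotypes; failing", snp_id)
        return SnpQcRecord(snp_id, counts, float("nan"), float("nan"), False)
    maf = minor_allele_frequency(counts)
    hwe = hwe_exact_p(counts)
    passed = (hwe >= hwe_threshold) and (maf >= maf_threshold)
    return SnpQcRecord(snp_id, counts, maf, hwe, passed)


def qc_filter(
    genotypes: GenotypeMatrix,
    hwe_threshold: float = 0.2,
    maf_threshold: float = 0.05,
) -> tuple[list[str], list[SnpQcRecord]]:
    """Exclude SNPs with HWE p below ``hwe_threshold`` or MAF below
    ``maf_threshold`` (strict-< exclusion; values equal to a threshold pass).

    Returns the ordered list of passing SNP ids and the full QC table.
    """
    for t in (hwe_threshold, maf_threshold):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    records = [
        snp_qc_record(sid, genotypes.dosage[:, j], hwe_threshold, maf_threshold)
        for j, sid in enumerate(genotypes.snp_ids)
    ]
    passing = [r.snp_id for r in records if r.passed]
    logger.info("QC: %d / %d SNPs pass (HWE p >= %g, MAF >= %g)",
                len(passing), len(records), hwe_threshold, maf_threshold)
    return passing, records


def write_qc_tsv(records: list[SnpQcRecord], path: str | Path) -> None:
    rows = [
        {
            "snp_id": r.snp_id,
            "n_hom_minor": r.genotype_counts[0],
            "n_het": r.genotype_counts[1],
            "n_hom_major": r.genotype_counts[2],
            "maf": r.maf,
            "hwe_p": r.hwe_p,
            "pass": int(r.passed),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
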