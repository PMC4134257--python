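"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a small pharmacogenomic case-control study: a
cohort of diploid patients genotyped at independent biallelic SNPs drawn
under Hardy-Weinberg equilibrium, genes annotated with GO terms (a
configurable fraction carrying a term from the target list), a binary
adverse-event endpoint drawn from a logistic model with optional causal
SNPs and clinical covariates, and a nested monotherapy subset assigned
independently of everything else (the exchangeability the permutation
scheme assumes).  Defaults mirror a cohort of 168 patients with a
53-patient monotherapy subset and a marginal event rate near 36/168.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from snpscreen.core_data import (
    CohortTable,
    GenotypeMatrix,
    SnpAnnotation,
    write_annotation_tsv,
    write_gene_go_tsv,
    write_genotypes_tsv,
    write_phenotypes_tsv,
    write_term_list,
)

TARGET_TERM_POOL_START = 5215  # accessions GO:0005215, GO:0005216, ... are targets
DECOY_TERM_POOL_START = 8150


@dataclass
class CovariateSpec:
    """One clinical covariate: binary (prevalence), ordinal over {0,1,2}
    (probabilities), or continuous standard normal; log_or is its effect
    on the outcome logit per unit."""

    kind: str  # binary | ordinal | continuous
    log_or: float = 0.0
    prevalence: float = 0.5           # binary
    probs: tuple[float, float, float] = (0.5, 0.4, 0.1)  # ordinal

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class SyntheticConfig:
    """Full generative specification of a synthetic study."""

    n_patients: int = 168
    monotherapy_fraction: float = 53 / 168
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int | None = None          # default: one gene per 5 SNPs
    target_gene_fraction: float = 0.6   # genes carrying a target GO term
    intergenic_fraction: float = 0.05   # SNPs with no gene annotation
    n_target_terms: int = 8
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    baseline_logit: float = math.log(36 / 132)  # event rate ~ 36/168
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    missing_rate: float = 0.0
    ld_block_size: int = 1              # >1 switches on block correlation
    ld_block_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.monotherapy_fraction, self.target_gene_fraction,
                     self.intergenic_fraction, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        for idx, _ in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} outside [0, n_snps)")
        if not -1.0 < self.ld_block_r < 1.0:
            raise ValueError("LD block correlation must lie in (-1, 1)")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    annotation: dict[str, SnpAnnotation]
    gene_go: dict[str, set[str]]
    target_terms: list[str]
    cohort: CohortTable
    config: SyntheticConfig


def _draw_dosages(rng: np.random.Generator, mafs: np.ndarray, n: int,
                  block_size: int, block_r: float) -> np.ndarray:
    """HWE dosages; optional Gaussian-copula block correlation between SNPs."""
    m = len(mafs)
    if block_size <= 1 or block_r == 0.0:
        return rng.binomial(2, mafs, size=(n, m)).astype(float)
    # two independent chromosomes per patient; each is a thresholded
    # latent normal sharing a per-block factor with correlation block_r
    dosage = np.zeros((n, m))
    for _ in range(2):
        z = np.empty((n, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, stop - start))
            z[:, start:stop] = math.sqrt(abs(block_r)) * np.sign(block_r) * shared \
                + math.sqrt(1 - abs(block_r)) * own
        from scipy.stats import norm
        dosage += (norm.cdf(z) < mafs).astype(float)
    return dosage


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one fully reproducible synthetic study from ``config``.

    Genotypes are drawn per SNP under HWE at a MAF uniform over
    ``maf_range``; columns are re-oriented so the stored dosage counts the
    sample minor allele of the full cohort.  The outcome follows
    logit P(event) = baseline + sum(beta_snp * dosage) + sum(beta_cov * x).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_patients, config.n_snps

    mafs = rng.uniform(*config.maf_range, size=m)
    dosage = _draw_dosages(rng, mafs, n, config.ld_block_size, config.ld_block_r)

    # orient each column to the sample minor allele (ties keep orientation)
    freq = dosage.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    # covariates
    cov_values: dict[str, np.ndarray] = {}
    for name, spec in config.covariates.items():
        if spec.kind == "binary":
            cov_values[name] = rng.binomial(1, spec.prevalence, size=n).astype(float)
        elif spec.kind == "ordinal":
            cov_values[name] = rng.choice([0.0, 1.0, 2.0], size=n, p=spec.probs)
        else:
            cov_values[name] = rng.standard_normal(n)

    # outcome from the logistic model on true (pre-missingness) dosages
    logit = np.full(n, config.baseline_logit)
    for idx, beta in config.causal_snps:
        logit += beta * dosage[:, idx]
    for name, spec in config.covariates.items():
        logit += spec.log_or * cov_values[name]
    outcome = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))).astype(int)

    # adverse-event grades consistent with the dichotomized endpoint
    grades = np.where(outcome == 1,
                      rng.choice([2, 3, 4], size=n, p=[0.7, 0.2, 0.1]),
                      rng.choice([0, 1], size=n, p=[0.6, 0.4])).astype(float)

    # nested monotherapy subset, independent of genotype and outcome
    n_mono = int(round(config.monotherapy_fraction * n))
    mono = np.zeros(n, dtype=bool)
    mono[rng.permutation(n)[:n_mono]] = True

    # genotype missingness applied to the observed matrix only
    observed = dosage.copy()
    if config.missing_rate > 0:
        observed[rng.random((n, m)) < config.missing_rate] = np.nan

    patient_ids = [f"P{i:04d}" for i in range(n)]
    snp_ids = [f"rs{1000000 + j}" for j in range(m)]
    genotypes = GenotypeMatrix(patient_ids, snp_ids, observed,
                               [("A", "C")] * m)

    # gene / GO structure
    n_genes = config.n_genes if config.n_genes is not None else max(1, m // 5)
    n_target_genes = int(round(config.target_gene_fraction * n_genes))
    target_terms = [f"GO:{TARGET_TERM_POOL_START + t:07d}"
                    for t in range(config.n_target_terms)]
    gene_go: dict[str, set[str]] = {}
    for g in range(n_genes):
        gene = f"GENE{g:04d}"
        if g < n_target_genes:
            gene_go[gene] = {target_terms[g % config.n_target_terms]}
        else:
            gene_go[gene] = {f"GO:{DECOY_TERM_POOL_START + g:07d}"}

    n_intergenic = int(round(config.intergenic_fraction * m))
    annotation: dict[str, SnpAnnotation] = {}
    for j, sid in enumerate(snp_ids):
        intergenic = j >= m - n_intergenic
        genes = frozenset() if intergenic else frozenset({f"GENE{j % n_genes:04d}"})
        annotation[sid] = SnpAnnotation(
            snp_id=sid,
            chromosome=str(1 + j % 22),
            position=1000 + 977 * j,
            gene_symbols=genes,
            location_class="intergenic" if intergenic else "intron",
        )

    cohort = CohortTable(
        patient_ids=patient_ids,
        outcome=outcome,
        monotherapy=mono,
        grades=pd.DataFrame({"diarrhea_grade": grades}),
        covariates=pd.DataFrame(cov_values),
    )
    return SyntheticCohort(genotypes, annotation, gene_go, target_terms, cohort, config)


def generate_null_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Same generative process with every genotype effect removed, for
    family-wise error calibration."""
    null_cfg = dataclasses.replace(config, causal_snps=[])
    return generate_cohort(null_cfg)


def write_dataset(bundle: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the plain-text dialects the readers accept,
    plus a manifest recording the full config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_go": outdir / "gene_go.tsv",
        "term_list": outdir / "target_terms.txt",
        "phenotypes": outdir / "phenotypes.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_genotypes_tsv(bundle.genotypes, paths["genotypes"])
    write_annotation_tsv(bundle.annotation, paths["annotation"])
    write_gene_go_tsv(bundle.gene_go, paths["gene_go"])
    write_term_list(bundle.target_terms, paths["term_list"])
    write_phenotypes_tsv(bundle.cohort, paths["phenotypes"])
    cfg = dataclasses.asdict(bundle.config)
    cfg["covariates"] = {k: dataclasses.asdict(v)
                         for k, v in bundle.config.covariates.items()}
    paths["manifest"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths
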