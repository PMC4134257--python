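"""Domain containers and plain-text readers/writers.

Genotypes are stored as minor-allele dosages: for every biallelic SNP each
patient carries 0, 1 or 2 copies of the designated minor allele, with NaN
marking a missing call.  The minor allele is oriented on the full cohort
once and reused everywhere downstream, so stage-1 (subset) and stage-2
(full-cohort) statistics never disagree about which allele is counted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("snpscreen")

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")

LOCATION_CLASSES = {
    "intron",
    "NearGene-5",
    "5'UTR",
    "3'UTR",
    "coding",
    "intergenic",
    "other",
}


@dataclass
class GenotypeMatrix:
    """Patients x SNPs diploid minor-allele dosage matrix.

    Parameters
    ----------
    patient_ids
        Opaque unique patient identifiers, one per row.
    snp_ids
        Unique rs identifiers, one per column.
    dosage
        Float matrix with entries in {0, 1, 2, NaN}; NaN is a missing call.
    allele_labels
        Optional per-SNP ``(minor_base, major_base)`` pairs.  The TSV
        dialect carries no allele information, so this may be ``None``.
    """

    patient_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    allele_labels: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.patient_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage value {self.dosage[tuple(bad)]!r} at patient "
                f"{self.patient_ids[bad[0]]!r}, SNP {self.snp_ids[bad[1]]!r} "
                "is not in {0, 1, 2, NaN}"
            )
        if self.allele_labels is not None:
            if len(self.allele_labels) != len(self.snp_ids):
                raise ValueError("allele_labels length mismatch")
            for sid, (minor, major) in zip(self.snp_ids, self.allele_labels):
                if minor == major:
                    raise ValueError(f"identical allele labels for {sid}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def select_patients(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row selection only; per-patient records are untouched."""
        mask = np.asarray(mask, dtype=bool)
        ids = [p for p, m in zip(self.patient_ids, mask) if m]
        return GenotypeMatrix(ids, list(self.snp_ids), self.dosage[mask], self.allele_labels)

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        labels = None
        if self.allele_labels is not None:
            labels = [self.allele_labels[i] for i in idx]
        return GenotypeMatrix(list(self.patient_ids), list(snp_ids), self.dosage[:, idx], labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.patient_ids, columns=self.snp_ids)


@dataclass(frozen=True)
class SnpAnnotation:
    """Chip-style annotation for one SNP (rs id, locus, genes, location class)."""

    snp_id: str
    chromosome: str
    position: int
    gene_symbols: frozenset[str]
    location_class: str = "other"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (1-based)")
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"{self.snp_id}: unknown location class {self.location_class!r}")


@dataclass
class CohortTable:
    """Per-patient outcomes, monotherapy membership, and clinical covariates.

    ``grades`` holds the highest recorded NCI-CTC grade (0-4) per adverse
    event type.  ``outcome`` is the dichotomized binary endpoint; patients
    with a missing endpoint grade are dropped at construction time.
    ``monotherapy`` flags membership in the nested first dataset.
    """

    patient_ids: list[str]
    outcome: np.ndarray
    monotherapy: np.ndarray
    grades: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.monotherapy = np.asarray(self.monotherapy, dtype=bool)
        n = len(self.patient_ids)
        if self.outcome.shape != (n,) or self.monotherapy.shape != (n,):
            raise ValueError("outcome / monotherapy length mismatch")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must be binary")
        if not self.grades.empty:
            vals = self.grades.to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 4))
            if not ok.all():
                raise ValueError("grades must lie in {0..4}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        ids = [p for p, m in zip(self.patient_ids, mask) if m]
        grades = self.grades.loc[mask] if not self.grades.empty else self.grades
        cov = self.covariates.loc[mask] if not self.covariates.empty else self.covariates
        return CohortTable(ids, self.outcome[mask], self.monotherapy[mask],
                           grades.reset_index(drop=True), cov.reset_index(drop=True))

    def monotherapy_subset(self) -> "CohortTable":
        return self.subset(self.monotherapy)


def dichotomize_grades(grades: Sequence[float] | pd.Series, threshold: int) -> pd.Series:
    """Binary endpoint: 1 iff the highest recorded grade is >= ``threshold``.

    Patients with a missing grade are excluded (logged).  Returns a Series
    indexed like the input (positional index for plain sequences).
    """
    if threshold not in (1, 2, 3, 4):
        raise ValueError("threshold must be in {1..4}")
    s = pd.Series(grades, dtype=float) if not isinstance(grades, pd.Series) else grades.astype(float)
    n_missing = int(s.isna().sum())
    if n_missing:
        logger.info("dichotomize_grades: excluding %d patient(s) with missing grade", n_missing)
    s = s.dropna()
    if not s.isin([0, 1, 2, 3, 4]).all():
        raise ValueError("grades must lie in {0..4}")
    return (s >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Genotype I/O


def _orient_minor(alt_dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, tuple[str, str]]:
    """Flip ALT dosages so the matrix counts the sample minor allele.

    A tie at frequency 0.5 is broken toward the alphabetically smaller base.
    """
    total = 2 * np.count_nonzero(~np.isnan(alt_dosage))
    alt_count = np.nansum(alt_dosage)
    if total == 0:
        return alt_dosage, (alt, ref)
    freq = alt_count / total
    if freq < 0.5:
        minor_is_alt = True
    elif freq > 0.5:
        minor_is_alt = False
    else:
        minor_is_alt = alt < ref
        logger.info("allele frequency tie at 0.5; alphabetic tie-break set %s as minor",
                    alt if minor_is_alt else ref)
    if minor_is_alt:
        return alt_dosage, (alt, ref)
    return 2.0 - alt_dosage, (ref, alt)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT only) into a minor-allele dosage matrix.

    Multiallelic or non-SNP records are skipped with a log entry.  The minor
    allele is decided per SNP from the sample allele frequency.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError on bad input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    patients = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.info("skipping non-biallelic-SNP record #%d at %s:%d", i, var.CHROM, var.POS)
            continue
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if sid in seen:
            raise ValueError(f"duplicate rs ID {sid!r} in {path} (record #{i})")
        seen.add(sid)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(var.gt_types, dtype=float)
        alt_dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dosage, pair = _orient_minor(alt_dosage, var.REF, var.ALT[0])
        snp_ids.append(sid)
        columns.append(dosage)
        labels.append(pair)
    if not columns:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(patients, snp_ids, np.column_stack(columns), labels)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype TSV dialect: header ``patient_id<TAB>rs...``,
    cells in {0,1,2,NA} already oriented to minor-allele dosage."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty genotype table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated patient ID {dup!r}")
    mat = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if isinstance(cell, float) and np.isnan(cell):
                cell = "NA"
            cell = str(cell).strip()
            if cell in ("NA", "nan", ""):
                mat[i, j] = np.nan
            elif cell in ("0", "1", "2"):
                mat[i, j] = float(cell)
            else:
                raise ValueError(
                    f"{path}: invalid cell {cell!r} at patient {df.index[i]!r}, SNP {col!r}"
                )
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), mat)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation / ontology-map / phenotype I/O


def read_annotation_tsv(path: str | Path) -> dict[str, SnpAnnotation]:
    """Annotation TSV: snp_id, chromosome, position, gene_symbols
    (comma-separated, may be empty), location_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "chromosome", "position", "gene_symbols", "location_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    out: dict[str, SnpAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.snp_id in out:
            raise ValueError(f"{path}: duplicate annotation for {row.snp_id}")
        genes = frozenset(
            g.strip() for g in str(row.gene_symbols or "").split(",") if g and g.strip()
        ) if pd.notna(row.gene_symbols) else frozenset()
        out[row.snp_id] = SnpAnnotation(
            snp_id=row.snp_id,
            chromosome=str(row.chromosome),
            position=int(row.position),
            gene_symbols=genes,
            location_class=str(row.location_class),
        )
    return out


def write_annotation_tsv(annotations: Mapping[str, SnpAnnotation], path: str | Path) -> None:
    rows = [
        {
            "snp_id": a.snp_id,
            "chromosome": a.chromosome,
            "position": a.position,
            "gene_symbols": ",".join(sorted(a.gene_symbols)),
            "location_class": a.location_class,
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column map ``gene<TAB>GO:NNNNNNN``, one association per line."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>GO:NNNNNNN'")
            gene, acc = parts
            if not GO_ACCESSION_RE.match(acc):
                raise ValueError(f"{path}:{lineno}: malformed GO accession {acc!r}")
            mapping.setdefault(gene, set()).add(acc)
    return mapping


def write_gene_go_tsv(mapping: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for acc in sorted(mapping[gene]):
                fh.write(f"{gene}\t{acc}\n")


def read_term_list(path: str | Path) -> list[str]:
    """Target GO term list: one accession per line, order-preserving, unique."""
    terms: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            acc = line.strip()
            if not acc or acc.startswith("#"):
                continue
            if not GO_ACCESSION_RE.match(acc):
                raise ValueError(f"{path}:{lineno}: malformed GO accession {acc!r}")
            if acc not in seen:
                seen.add(acc)
                terms.append(acc)
    if not terms:
        raise ValueError(f"{path}: empty term list")
    return terms


def write_term_list(terms: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write(f"{t}\n")


def read_phenotypes_tsv(
    path: str | Path,
    endpoint_event: str = "diarrhea",
    grade_threshold: int = 2,
) -> CohortTable:
    """Phenotype/covariate TSV into a :class:`CohortTable`.

    Expected columns: ``patient_id``, ``monotherapy`` (0/1), one
    ``<event>_grade`` column per adverse-event type, and any further
    columns treated as covariates.  The endpoint is dichotomized as
    grade >= ``grade_threshold`` for ``endpoint_event``; patients with a
    missing endpoint grade are dropped (logged).
    """
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns or "monotherapy" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs patient_id and monotherapy columns")
    grade_cols = [c for c in df.columns if c.endswith("_grade")]
    endpoint_col = f"{endpoint_event}_grade"
    if endpoint_col not in grade_cols:
        raise ValueError(f"{path}: no {endpoint_col} column for the requested endpoint")
    outcome = dichotomize_grades(df[endpoint_col], grade_threshold)
    kept = df.loc[outcome.index]
    cov_cols = [c for c in df.columns
                if c not in ("patient_id", "monotherapy") and c not in grade_cols]
    return CohortTable(
        patient_ids=list(kept["patient_id"].astype(str)),
        outcome=outcome.to_numpy(),
        monotherapy=kept["monotherapy"].astype(int).to_numpy().astype(bool),
        grades=kept[grade_cols].reset_index(drop=True),
        covariates=kept[cov_cols].reset_index(drop=True),
    )


def write_phenotypes_tsv(cohort: CohortTable, path: str | Path,
                         endpoint_event: str = "diarrhea") -> None:
    df = pd.DataFrame({"patient_id": cohort.patient_ids,
                       "monotherapy": cohort.monotherapy.astype(int)})
    if not cohort.grades.empty:
        df = pd.concat([df, cohort.grades.reset_index(drop=True)], axis=1)
    else:
        # the dichotomized outcome is re-derivable iff a grade column exists
        df[f"{endpoint_event}_grade"] = np.where(cohort.outcome == 1, 2, 0)
    if not cohort.covariates.empty:
        df = pd.concat([df, cohort.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)
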