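"""End-to-end orchestration: KB selection -> QC -> two-stage screen ->
permutation correction -> BH q-values -> model comparison, with
Table-style reports and a deterministic run log.

The report bundle is a pure function of (inputs, config, seed): no
timestamps or machine state enter any output, and the resolved
configuration hash is embedded in the run log for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from snpscreen import association, kb_snp, multiplicity, qc_filters
from snpscreen.core_data import (
    CohortTable,
    GenotypeMatrix,
    read_annotation_tsv,
    read_gene_go_tsv,
    read_genotypes_tsv,
    read_genotypes_vcf,
    read_phenotypes_tsv,
    read_term_list,
)
from snpscreen.modeling import compare_models
from snpscreen.two_stage import (
    PermutationNull,
    ScreenConfig,
    ScreenResult,
    TwoStageEngine,
    adjusted_p,
    write_null_tsv,
)

TOP_SNP_TOKEN = "@top"


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    genotypes: str
    annotation: str
    gene_go: str
    term_list: str
    phenotypes: str
    output_dir: str
    endpoint_event: str = "diarrhea"
    grade_threshold: int = 2
    hwe_threshold: float = 0.2
    maf_threshold: float = 0.05
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    model_specs: list[list[str]] = field(default_factory=lambda: [[TOP_SNP_TOKEN]])

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        screen_raw = raw.pop("screen", {})
        cfg = cls(**raw)
        if screen_raw:
            cfg.screen = ScreenConfig(**screen_raw)
        return cfg

    def resolved(self) -> dict:
        # output_dir is excluded so the provenance hash identifies the
        # analysis, not where its reports happen to land
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    association: pd.DataFrame
    screen: pd.DataFrame
    qc: pd.DataFrame
    models: pd.DataFrame
    covariates_first: pd.DataFrame
    covariates_second: pd.DataFrame
    null: PermutationNull
    funnel: dict[str, int]
    paths: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("read-inputs")
def _read_inputs(config: PipelineConfig) -> tuple[GenotypeMatrix, dict, dict, list, CohortTable]:
    gpath = Path(config.genotypes)
    if gpath.suffix in (".vcf", ".gz") or gpath.name.endswith(".vcf.gz"):
        genotypes = read_genotypes_vcf(gpath)
    else:
        genotypes = read_genotypes_tsv(gpath)
    annotation = read_annotation_tsv(config.annotation)
    gene_go = read_gene_go_tsv(config.gene_go)
    terms = read_term_list(config.term_list)
    cohort = read_phenotypes_tsv(config.phenotypes, config.endpoint_event,
                                 config.grade_threshold)
    # align genotype rows to the analyzed cohort (endpoint-missing dropped)
    idx = {p: i for i, p in enumerate(genotypes.patient_ids)}
    missing = [p for p in cohort.patient_ids if p not in idx]
    if missing:
        raise ValueError(f"patients without genotypes: {missing[:5]}")
    mask = np.zeros(genotypes.n_patients, dtype=bool)
    order = [idx[p] for p in cohort.patient_ids]
    mask[order] = True
    aligned = GenotypeMatrix(
        [genotypes.patient_ids[i] for i in order],
        list(genotypes.snp_ids),
        genotypes.dosage[order],
        genotypes.allele_labels,
    )
    return aligned, annotation, gene_go, terms, cohort


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in order and write the full report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genotypes, annotation, gene_go, terms, cohort = _read_inputs(config)
    funnel = {"genotyped_snps": genotypes.n_snps,
              "analyzed_patients": cohort.n_patients,
              "first_dataset_patients": int(cohort.monotherapy.sum())}

    selection = _stage("kb-snp")(kb_snp.select_snps_by_go)(
        {s: a for s, a in annotation.items() if s in set(genotypes.snp_ids)},
        gene_go, terms)
    kb_ids = [s for s in genotypes.snp_ids if s in set(selection.selected_snp_ids)]
    funnel["kb_selected"] = len(kb_ids)
    if not kb_ids:
        raise PipelineError("stage 'kb-snp' failed: empty selection")

    kb_matrix = genotypes.select_snps(kb_ids)
    passing, qc_records = _stage("qc")(qc_filters.qc_filter)(
        kb_matrix, config.hwe_threshold, config.maf_threshold)
    funnel["qc_passed"] = len(passing)
    if not passing:
        raise PipelineError("stage 'qc' failed: no SNP passes QC")

    engine = TwoStageEngine(genotypes, cohort, passing, config.screen)
    screen_result: ScreenResult = _stage("two-stage-screen")(engine.observed)()
    funnel["stage1_selected"] = len(screen_result.stage1_selected)

    null = _stage("permutation")(engine.permute)()
    p_per = {sid: adjusted_p(p2, null) for sid, p2 in screen_result.stage2_p.items()}
    funnel["significant_p_per"] = sum(1 for v in p_per.values() if v < 0.05)

    # single-stage scan on the full dataset for the BH table (m = all
    # QC-passing candidates, not just stage-1 survivors)
    p_full = engine.stage2.pvalues(engine.outcome)
    qtable = _stage("bh")(multiplicity.bh_qvalues)(dict(zip(passing, p_full)))

    qc_by_id = {r.snp_id: r for r in qc_records}
    assoc_rows = []
    for sid, p_F, q in zip(qtable["snp_id"], qtable["p_F"], qtable["q_BH"]):
        ann = annotation[sid]
        rec = qc_by_id[sid]
        labels = None
        if genotypes.allele_labels is not None:
            labels = genotypes.allele_labels[genotypes.snp_ids.index(sid)]
        assoc_rows.append({
            "snp_id": sid,
            "allele": f"{labels[0]}/{labels[1]}" if labels else "NA",
            "maf": rec.maf,
            "location": ann.location_class,
            "chromosome": ann.chromosome,
            "position": ann.position,
            "gene": ",".join(sorted(ann.gene_symbols)) or "NA",
            "p_F": p_F,
            "q_BH": q,
            "p_stage1": screen_result.stage1_selected.get(sid, np.nan),
            "p_per": p_per.get(sid, np.nan),
        })
    assoc = pd.DataFrame(assoc_rows).sort_values(
        ["p_F", "snp_id"], kind="stable").reset_index(drop=True)

    screen_df = pd.DataFrame(
        [{"snp_id": sid,
          "p_stage1": screen_result.stage1_selected[sid],
          "p_stage2": screen_result.stage2_p[sid],
          "p_per": p_per[sid]} for sid in screen_result.stage2_p],
        columns=["snp_id", "p_stage1", "p_stage2", "p_per"],
    ).sort_values(["p_stage2", "snp_id"], kind="stable").reset_index(drop=True)

    cov_first = association.covariate_scan(cohort, "first")
    cov_second = association.covariate_scan(cohort, "second")

    # model comparison on the full dataset; "@top" = best stage-2 SNP
    # (falls back to the smallest single-stage p when nothing survives)
    if screen_result.stage2_p:
        top = min(screen_result.stage2_p, key=screen_result.stage2_p.get)
    else:
        top = assoc.iloc[0]["snp_id"]
    data = cohort.covariates.copy()
    data[top] = genotypes.dosage[:, genotypes.snp_ids.index(top)]
    specs = [[top if t == TOP_SNP_TOKEN else t for t in spec]
             for spec in config.model_specs]
    models = _stage("modeling")(compare_models)(specs, data, cohort.outcome)

    paths = {
        "association": outdir / "association_report.tsv",
        "screen": outdir / "screen_report.tsv",
        "qc": outdir / "qc_report.tsv",
        "models": outdir / "model_comparison.tsv",
        "covariates_first": outdir / "covariate_scan_first.tsv",
        "covariates_second": outdir / "covariate_scan_second.tsv",
        "null": outdir / "permutation_null.tsv",
        "run_log": outdir / "run_log.txt",
    }
    float_fmt = "%.10g"
    assoc.to_csv(paths["association"], sep="\t", index=False, float_format=float_fmt)
    screen_df.to_csv(paths["screen"], sep="\t", index=False, float_format=float_fmt)
    qc_filters.write_qc_tsv(qc_records, paths["qc"])
    models.to_csv(paths["models"], sep="\t", index=False, float_format=float_fmt)
    cov_first.to_csv(paths["covariates_first"], sep="\t", index=False, float_format=float_fmt)
    cov_second.to_csv(paths["covariates_second"], sep="\t", index=False, float_format=float_fmt)
    write_null_tsv(null, paths["null"])

    with open(paths["run_log"], "w") as fh:
        fh.write(f"config_hash\t{config.digest()}\n")
        fh.write(f"seed\t{config.screen.seed}\n")
        fh.write(f"n_perm\t{config.screen.n_perm}\n")
        fh.write(f"alpha1\t{config.screen.alpha1}\n")
        fh.write(f"model\t{config.screen.model}\n")
        for key, val in funnel.items():
            fh.write(f"{key}\t{val}\n")
        fh.write(f"observed_min_p\t{screen_result.observed_min_p:.10g}\n")
        fh.write(f"top_snp\t{top}\n")

    return PipelineReport(assoc, screen_df,
                          pd.read_csv(paths["qc"], sep="\t"), models,
                          cov_first, cov_second, null, funnel, paths)
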