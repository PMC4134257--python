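"""Two-stage case-control screening and the min-p permutation correction.

Stage 1 tests every candidate SNP on the nested monotherapy subset (the
first dataset) with Fisher's exact test under the configured genetic
model and keeps those with p below ``alpha1``.  Stage 2 re-tests the
survivors on the full cohort (the second dataset, which contains the
first).  The family-wise correction replays BOTH stages on cohorts whose
outcome labels were shuffled across all patients of the full dataset:
each replay records the smallest stage-2 p-value among its own stage-1
survivors (1.0 when nothing survives), and the adjusted p-value of an
observed SNP is the plain fraction of null minima at or below its
observed stage-2 p.

The replay is exact but cheap: with labels shuffled and genotypes fixed,
a SNP's 2x2 table margins are fixed (up to the per-SNP missing pattern),
so every distinct margin triple is enumerated once and each permutation
reduces to one matrix-vector product plus table lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from snpscreen.association import FisherCache, _fisher_p_vector
from snpscreen.core_data import CohortTable, GenotypeMatrix

logger = logging.getLogger("snpscreen")


@dataclass
class ScreenConfig:
    """Screening configuration: stage-1 threshold, genetic model used in
    both screening stages, permutation count, and the master seed."""

    alpha1: float = 0.005
    model: str = "allele"
    n_perm: int = 100_000
    seed: int = 0
    stratified: bool = False  # shuffle within / across cohorts (default: across)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha1 < 1.0:
            raise ValueError("alpha1 must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class ScreenResult:
    stage1_selected: dict[str, float]  # snp_id -> stage-1 p (< alpha1)
    stage2_p: dict[str, float]         # snp_id -> stage-2 p (survivors only)
    observed_min_p: float


@dataclass
class PermutationNull:
    min_p_values: np.ndarray
    seed: int
    n_perm: int
    alpha1: float = 0.005

    def __post_init__(self) -> None:
        self.min_p_values = np.asarray(self.min_p_values, dtype=float)
        if len(self.min_p_values) != self.n_perm:
            raise ValueError("null length does not match n_perm")
        if not ((self.min_p_values > 0) & (self.min_p_values <= 1)).all():
            raise ValueError("null min-p values must lie in (0, 1]")


class _StageTester:
    """Vectorized Fisher tests of a fixed genotype block against arbitrary
    binary label vectors.

    SNPs without missing calls share one events margin per label count and
    are served by a flat precomputed lookup; SNPs with missing calls fall
    back to per-SNP cache lookups.
    """

    def __init__(self, dosage: np.ndarray, model: str, cache: FisherCache) -> None:
        d = np.asarray(dosage, dtype=float)
        miss = np.isnan(d)
        if model == "allele":
            units = np.where(miss, 0.0, d)
            self.unit_tot = 2
        elif model == "dominant":
            units = np.where(miss, 0.0, (d >= 1).astype(float))
            self.unit_tot = 1
        elif model == "recessive":
            units = np.where(miss, 0.0, (d == 2).astype(float))
            self.unit_tot = 1
        else:
            raise ValueError(f"unknown genetic model {model!r}")
        self.units = units
        self.notmiss = (~miss).astype(float)
        self.n_nonmiss = self.notmiss.sum(axis=0).astype(int)
        self.total = self.unit_tot * self.n_nonmiss          # N per SNP
        self.row1 = units.sum(axis=0).astype(int)            # minor units per SNP
        self.has_missing = miss.any(axis=0)
        self.clean = ~self.has_missing
        self.cache = cache
        self._flat: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _flat_tables(self, n_events: int):
        """Concatenated p-value lookup vectors for the no-missing SNPs at a
        given number of event patients (the margin fixed under shuffling)."""
        entry = self._flat.get(n_events)
        if entry is None:
            flats, offsets, lows = [], [], []
            pos = 0
            col1 = self.unit_tot * n_events
            for j in np.flatnonzero(self.clean):
                lo, vec = _fisher_p_vector(int(self.total[j]), int(self.row1[j]), col1)
                flats.append(vec)
                offsets.append(pos)
                lows.append(lo)
                pos += len(vec)
            entry = (
                np.concatenate(flats) if flats else np.empty(0),
                np.asarray(offsets, dtype=np.int64),
                np.asarray(lows, dtype=np.int64),
            )
            self._flat[n_events] = entry
        return entry

    def pvalues(self, y: np.ndarray) -> np.ndarray:
        """Two-sided Fisher p for every SNP against binary labels ``y``."""
        y = np.asarray(y, dtype=float)
        a = y @ self.units
        p = np.empty(self.units.shape[1])
        n_events = int(y.sum())
        if self.clean.any():
            flat, offsets, lows = self._flat_tables(n_events)
            idx = offsets + (np.rint(a[self.clean]).astype(np.int64) - lows)
            p[self.clean] = flat[idx]
        if self.has_missing.any():
            e = y @ self.notmiss
            for j in np.flatnonzero(self.has_missing):
                p[j] = self.cache.pvalue(
                    int(self.total[j]), int(self.row1[j]),
                    self.unit_tot * int(e[j]), int(round(a[j])),
                )
        return p


class TwoStageEngine:
    """Shared machinery for the observed screen and its permutation replay."""

    def __init__(self, genotypes: GenotypeMatrix, cohort: CohortTable,
                 snps: Sequence[str], config: ScreenConfig) -> None:
        if len(snps) == 0:
            raise ValueError("empty candidate SNP set")
        if list(genotypes.patient_ids) != list(cohort.patient_ids):
            raise ValueError("genotype and cohort patient ids differ")
        if not cohort.monotherapy.any():
            raise ValueError("first dataset (monotherapy subset) is empty")
        self.snp_ids = list(snps)
        self.config = config
        gm = genotypes.select_snps(self.snp_ids)
        self.mono_mask = cohort.monotherapy
        self.outcome = cohort.outcome.astype(float)
        cache = FisherCache()
        self.stage1 = _StageTester(gm.dosage[self.mono_mask], config.model, cache)
        self.stage2 = _StageTester(gm.dosage, config.model, cache)

    def screen(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Both stages for one label vector; returns (p1, selected mask,
        min stage-2 p among survivors, 1.0 when none survive)."""
        p1 = self.stage1.pvalues(y[self.mono_mask])
        sel = p1 < self.config.alpha1
        if not sel.any():
            return p1, sel, 1.0
        p2 = self.stage2.pvalues(y)
        return p1, sel, float(p2[sel].min())

    def observed(self) -> ScreenResult:
        y = self.outcome
        p1 = self.stage1.pvalues(y[self.mono_mask])
        sel = p1 < self.config.alpha1
        stage1_selected = {self.snp_ids[j]: float(p1[j]) for j in np.flatnonzero(sel)}
        if not sel.any():
            return ScreenResult(stage1_selected, {}, 1.0)
        p2 = self.stage2.pvalues(y)
        stage2_p = {self.snp_ids[j]: float(p2[j]) for j in np.flatnonzero(sel)}
        return ScreenResult(stage1_selected, stage2_p, float(min(stage2_p.values())))

    def permute(self) -> PermutationNull:
        cfg = self.config
        master = np.random.SeedSequence(cfg.seed)
        streams = master.spawn(cfg.n_perm)
        y = self.outcome
        mono = self.mono_mask
        mins = np.empty(cfg.n_perm)
        for i, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            if cfg.stratified:
                y_perm = y.copy()
                y_perm[mono] = rng.permutation(y[mono])
                y_perm[~mono] = rng.permutation(y[~mono])
            else:
                y_perm = rng.permutation(y)
            _, _, mins[i] = self.screen(y_perm)
            if (i + 1) % 1000 == 0:
                logger.info("permutation %d / %d", i + 1, cfg.n_perm)
        return PermutationNull(mins, cfg.seed, cfg.n_perm, cfg.alpha1)


def stage1_screen(genotypes: GenotypeMatrix, outcome: np.ndarray,
                  snps: Sequence[str], config: ScreenConfig) -> dict[str, float]:
    """First-stage screen on the (already restricted) first dataset:
    Fisher p per candidate SNP, keeping those with p < alpha1."""
    if len(snps) == 0:
        raise ValueError("empty candidate SNP set")
    gm = genotypes.select_snps(list(snps))
    tester = _StageTester(gm.dosage, config.model, FisherCache())
    p = tester.pvalues(np.asarray(outcome, dtype=float))
    return {sid: float(pv) for sid, pv in zip(snps, p) if pv < config.alpha1}


def run_two_stage(genotypes: GenotypeMatrix, cohort: CohortTable,
                  snps: Sequence[str], config: ScreenConfig) -> ScreenResult:
    """Observed two-stage screen: stage 1 on the monotherapy subset,
    stage 2 on the full cohort for stage-1 survivors only."""
    return TwoStageEngine(genotypes, cohort, snps, config).observed()


def permutation_null(genotypes: GenotypeMatrix, cohort: CohortTable,
                     snps: Sequence[str], config: ScreenConfig) -> PermutationNull:
    """Empirical null of the min stage-2 p under outcome-label shuffling.

    Labels are shuffled across all patients of the full dataset (the
    permuted first dataset is re-extracted from the permuted full
    cohort), both stages are replayed, and the smallest stage-2 p among
    that replay's survivors is recorded.  One master seed spawns a
    child stream per permutation, so results do not depend on execution
    order.
    """
    return TwoStageEngine(genotypes, cohort, snps, config).permute()


def adjusted_p(observed_p: float, null: PermutationNull) -> float:
    """Permutation-adjusted p: the plain fraction of null min-p values at
    or below the observed stage-2 p (k/N, no +1 correction, so 0.0 is
    possible and should be read as "< 1/n_perm")."""
    if not 0.0 < observed_p <= 1.0:
        raise ValueError("observed p must lie in (0, 1]")
    if null.n_perm == 0 or len(null.min_p_values) == 0:
        raise ValueError("empty permutation null")
    return float((null.min_p_values <= observed_p).sum() / null.n_perm)


def write_null_tsv(null: PermutationNull, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed\t{null.seed}\n")
        fh.write(f"# n_perm\t{null.n_perm}\n")
        fh.write(f"# alpha1\t{null.alpha1}\n")
        fh.write("min_p\n")
        for v in null.min_p_values:
            fh.write(f"{v:.17g}\n")


def read_null_tsv(path: str | Path) -> PermutationNull:
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, val = line[1:].strip().split("\t")
                meta[key] = val
            elif line and line != "min_p":
                values.append(float(line))
    return PermutationNull(np.asarray(values), int(meta["seed"]),
                           int(meta["n_perm"]), float(meta["alpha1"]))


def write_screen_tsv(result: ScreenResult, null: PermutationNull | None,
                     path: str | Path) -> None:
    import pandas as pd

    rows = []
    for sid, p1 in sorted(result.stage1_selected.items(), key=lambda kv: kv[1]):
        p2 = result.stage2_p.get(sid)
        row = {"snp_id": sid, "p_stage1": p1, "p_stage2": p2}
        if null is not None and p2 is not None:
            row["p_per"] = adjusted_p(p2, null)
        rows.append(row)
    cols = ["snp_id", "p_stage1", "p_stage2"] + (["p_per"] if null is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
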