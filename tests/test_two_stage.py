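import numpy as np
import pytest
from scipy.stats import ks_2samp

from snpscreen.core_data import CohortTable, GenotypeMatrix
from snpscreen.two_stage import (
    PermutationNull,
    ScreenConfig,
    TwoStageEngine,
    adjusted_p,
    permutation_null,
    read_null_tsv,
    run_two_stage,
    stage1_screen,
    write_null_tsv,
)

from _oracles import min_p_two_stage_naive


def _study(dosage, outcome, mono):
    n, m = dosage.shape
    gm = GenotypeMatrix([f"p{i}" for i in range(n)],
                        [f"rs{j}" for j in range(m)], dosage)
    cohort = CohortTable([f"p{i}" for i in range(n)], outcome, mono)
    return gm, cohort


class TestStage1:
    def test_null_snps_give_empty_selection(self, rng):
        d = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        y = np.array([0, 1] * 15)
        # balanced design with independent genotypes: nothing at p < 1e-6
        gm, _ = _study(d, y, np.ones(30, dtype=bool))
        cfg = ScreenConfig(alpha1=1e-6, n_perm=1)
        assert stage1_screen(gm, y, gm.snp_ids, cfg) == {}

    def test_perfectly_separating_snp_selected(self):
        d = np.array([2.0] * 8 + [0.0] * 8)[:, None]
        y = np.array([1] * 8 + [0] * 8)
        gm, _ = _study(d, y, np.ones(16, dtype=bool))
        cfg = ScreenConfig(alpha1=1e-3, n_perm=1)
        sel = stage1_screen(gm, y, gm.snp_ids, cfg)
        assert "rs0" in sel and sel["rs0"] < 1e-3

    def test_empty_candidate_set_rejected(self, rng):
        d = rng.binomial(2, 0.4, size=(20, 3)).astype(float)
        y = rng.integers(0, 2, 20)
        gm, _ = _study(d, y, np.ones(20, dtype=bool))
        with pytest.raises(ValueError, match="empty candidate"):
            stage1_screen(gm, y, [], ScreenConfig(n_perm=1))

    def test_causal_snp_usually_detected(self):
        # one strong causal SNP (log-OR 1.5, MAF 0.3) at the monotherapy
        # scale n=53: selected in clearly more than half of replicates
        from snpscreen.synthetic import SyntheticConfig, generate_cohort

        hits = 0
        reps = 30
        for r in range(reps):
            b = generate_cohort(SyntheticConfig(
                n_patients=53, monotherapy_fraction=1.0, n_snps=20,
                maf_range=(0.3, 0.3), causal_snps=[(0, 1.5)], seed=7000 + r))
            sel = stage1_screen(b.genotypes, b.cohort.outcome,
                                b.genotypes.snp_ids, ScreenConfig(n_perm=1))
            hits += "rs1000000" in sel
        assert hits > reps / 2


class TestRunTwoStage:
    def _screened(self, rng, m=8, causal=False):
        n = 60
        d = rng.binomial(2, 0.35, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n)
        if causal:
            y = (d[:, 0] + rng.normal(0, 0.8, n) > 1.2).astype(int)
        mono = np.zeros(n, dtype=bool)
        mono[:24] = True
        return _study(d, y, mono)

    def test_no_survivor_min_p_is_one(self, rng):
        gm, cohort = self._screened(rng)
        res = run_two_stage(gm, cohort, gm.snp_ids, ScreenConfig(alpha1=1e-9, n_perm=1))
        assert res.stage1_selected == {} and res.observed_min_p == 1.0

    def test_min_p_is_smallest_stage2_p(self, rng):
        gm, cohort = self._screened(rng, causal=True)
        res = run_two_stage(gm, cohort, gm.snp_ids,
                            ScreenConfig(alpha1=0.5, n_perm=1))
        assert res.stage2_p
        assert res.observed_min_p == min(res.stage2_p.values())
        assert all(p < 0.5 for p in res.stage1_selected.values())

    def test_matches_naive_reimplementation(self, rng):
        # independent loop-over-SNPs/scipy oracle, incl. missing calls
        for trial in range(5):
            n, m = 50, 12
            d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
            d[rng.random((n, m)) < 0.05] = np.nan
            y = rng.integers(0, 2, n)
            mono = np.zeros(n, dtype=bool)
            mono[rng.permutation(n)[:20]] = True
            gm, cohort = _study(d, y, mono)
            res = run_two_stage(gm, cohort, gm.snp_ids,
                                ScreenConfig(alpha1=0.3, n_perm=1))
            expected = min_p_two_stage_naive(d, y, mono, 0.3)
            assert res.observed_min_p == pytest.approx(expected, rel=1e-7)


class TestPermutationNull:
    def test_single_permutation_in_unit_interval(self, null_cohort):
        b = null_cohort
        null = permutation_null(b.genotypes, b.cohort, b.genotypes.snp_ids,
                                ScreenConfig(n_perm=1, seed=3))
        assert len(null.min_p_values) == 1
        assert 0 < null.min_p_values[0] <= 1

    def test_fixed_seed_reproducible(self, null_cohort):
        b = null_cohort
        cfg = ScreenConfig(n_perm=50, seed=11)
        n1 = permutation_null(b.genotypes, b.cohort, b.genotypes.snp_ids, cfg)
        n2 = permutation_null(b.genotypes, b.cohort, b.genotypes.snp_ids, cfg)
        np.testing.assert_array_equal(n1.min_p_values, n2.min_p_values)

    def test_null_distribution_stable_across_seeds(self, null_cohort):
        # two independent permutation nulls estimate the same distribution
        b = null_cohort
        snps = b.genotypes.snp_ids
        a = permutation_null(b.genotypes, b.cohort, snps,
                             ScreenConfig(n_perm=2000, seed=101))
        c = permutation_null(b.genotypes, b.cohort, snps,
                             ScreenConfig(n_perm=2000, seed=202))
        assert ks_2samp(a.min_p_values, c.min_p_values).pvalue > 0.01

    def test_stratified_option_preserves_subset_counts(self, null_cohort):
        b = null_cohort
        null = permutation_null(b.genotypes, b.cohort, b.genotypes.snp_ids,
                                ScreenConfig(n_perm=20, seed=5, stratified=True))
        assert len(null.min_p_values) == 20

    def test_round_trip_tsv(self, tmp_path, null_cohort):
        b = null_cohort
        null = permutation_null(b.genotypes, b.cohort, b.genotypes.snp_ids,
                                ScreenConfig(n_perm=25, seed=9))
        path = tmp_path / "null.tsv"
        write_null_tsv(null, path)
        back = read_null_tsv(path)
        np.testing.assert_allclose(back.min_p_values, null.min_p_values)
        assert (back.seed, back.n_perm) == (9, 25)


class TestAdjustedP:
    NULL = PermutationNull(np.linspace(0.001, 1.0, 1000), seed=0, n_perm=1000)

    def test_plain_proportion(self):
        null = PermutationNull(
            np.concatenate([np.full(2891, 0.01), np.full(97109, 0.9)]),
            seed=0, n_perm=100_000)
        assert adjusted_p(0.02891, null) == pytest.approx(0.02891)

    def test_zero_possible_without_plus_one(self):
        assert adjusted_p(1e-9, self.NULL) == 0.0

    def test_all_below_gives_one(self):
        assert adjusted_p(1.0, self.NULL) == 1.0

    def test_nondecreasing_in_observed_p(self):
        ps = [adjusted_p(x, self.NULL) for x in np.linspace(0.01, 1.0, 37)]
        assert all(q1 <= q2 for q1, q2 in zip(ps, ps[1:]))

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            adjusted_p(0.5, PermutationNull(np.array([]), seed=0, n_perm=0))
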