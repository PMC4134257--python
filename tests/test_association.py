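import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from snpscreen.association import (
    ContingencyTable2x2,
    build_contingency,
    covariate_scan,
    fisher_exact_two_sided,
    odds_ratio_ci,
    spearman_tied,
)

from _oracles import fisher_two_sided_exact


class TestBuildContingency:
    DOSAGES = np.array([0, 1, 2, 2], dtype=float)
    OUTCOME = np.array([0, 0, 1, 1])

    def test_recessive(self):
        t = build_contingency(self.DOSAGES, self.OUTCOME, "recessive")
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)
        assert t.total == 4

    def test_dominant(self):
        t = build_contingency(self.DOSAGES, self.OUTCOME, "dominant")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 1)

    def test_allele_counts_chromosomes(self):
        t = build_contingency(self.DOSAGES, self.OUTCOME, "allele")
        assert (t.a, t.b, t.c, t.d) == (4, 1, 0, 3)
        assert t.total == 2 * len(self.DOSAGES)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(np.array([]), np.array([]), "allele")


class TestFisherTwoSided:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_perfect_separation(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-10)

    def test_rare_exposure_layout(self):
        # 2 exposed patients, both events, against a 34/132 background
        table = ContingencyTable2x2(2, 0, 34, 132)
        expected = float(fisher_two_sided_exact(2, 0, 34, 132))
        assert fisher_exact_two_sided(table) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("cells", [(0, 0, 3, 4), (3, 4, 0, 0), (0, 3, 0, 4)])
    def test_degenerate_margin_is_one(self, cells):
        assert fisher_exact_two_sided(ContingencyTable2x2(*cells)) == 1.0

    def test_symmetry_under_transposition_and_double_swap(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            p_t = fisher_exact_two_sided(ContingencyTable2x2(a, c, b, d))
            p_s = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a))
            assert p == pytest.approx(p_t, rel=1e-9)
            assert p == pytest.approx(p_s, rel=1e-9)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7)


class TestOddsRatio:
    def test_plain_formula(self):
        orr, _ = odds_ratio_ci(ContingencyTable2x2(10, 5, 5, 10))
        assert orr == pytest.approx(4.0)

    def test_unit_table_ci_brackets_one(self):
        orr, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(1, 1, 1, 1))
        assert orr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_haldane_correction_on_zero_cell(self):
        orr, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(2, 0, 34, 132))
        assert orr == pytest.approx((2.5 * 132.5) / (0.5 * 34.5), rel=1e-12)
        assert lo < orr < hi

    def test_no_haldane_gives_infinite_or(self):
        orr, ci = odds_ratio_ci(ContingencyTable2x2(2, 0, 34, 132), haldane=False)
        assert math.isinf(orr)
        assert all(math.isnan(v) for v in ci)

    def test_uncorrected_invariant_under_transposition(self):
        t1 = ContingencyTable2x2(7, 3, 2, 9)
        t2 = ContingencyTable2x2(7, 2, 3, 9)
        assert odds_ratio_ci(t1)[0] == pytest.approx(odds_ratio_ci(t2)[0])

    def test_haldane_converges_to_uncorrected_as_cells_grow(self):
        for scale in (1, 10, 100):
            t = ContingencyTable2x2(10 * scale, 5 * scale, 5 * scale, 10 * scale)
            corrected = ((10 * scale + 0.5) * (10 * scale + 0.5)) / (
                (5 * scale + 0.5) ** 2)
            assert abs(odds_ratio_ci(t)[0] - 4.0) <= abs(corrected - 4.0) + 1e-12


class TestSpearmanTied:
    def test_identity_all_distinct(self):
        x = np.arange(10, dtype=float)
        rho, p = spearman_tied(x, x)
        assert rho == 1.0 and p == 0.0

    def test_binary_binary_equals_phi(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, size=40).astype(float)
            y = rng.integers(0, 2, size=40).astype(float)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            n11 = np.sum((x == 1) & (y == 1))
            n00 = np.sum((x == 0) & (y == 0))
            n10 = np.sum((x == 1) & (y == 0))
            n01 = np.sum((x == 0) & (y == 1))
            phi = (n11 * n00 - n10 * n01) / math.sqrt(
                (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
            rho, _ = spearman_tied(x, y)
            assert rho == pytest.approx(phi, abs=1e-12)

    def test_constant_vector_reports_nan(self):
        rho, p = spearman_tied([1, 1, 1, 1], [0, 1, 0, 1])
        assert math.isnan(rho) and math.isnan(p)

    def test_pairwise_complete_filtering(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, np.nan]
        rho, p = spearman_tied(x, y)
        assert rho == 1.0 and p == 0.0


class TestCovariateScan:
    def test_constant_covariate_reported_na(self, small_cohort):
        cohort = small_cohort.cohort
        cohort.covariates["always_zero"] = 0.0
        try:
            out = covariate_scan(cohort, "second")
            row = out[out["covariate"] == "always_zero"].iloc[0]
            assert math.isnan(row["rho"]) and math.isnan(row["p"])
        finally:
            cohort.covariates.drop(columns="always_zero", inplace=True)

    def test_rows_match_direct_calls(self):
        import pandas as pd

        from snpscreen.core_data import CohortTable

        rng = np.random.default_rng(5)
        n = 60
        cov = pd.DataFrame({"x1": rng.integers(0, 2, n).astype(float),
                            "x2": rng.standard_normal(n)})
        cohort = CohortTable([f"p{i}" for i in range(n)],
                             rng.integers(0, 2, n), np.zeros(n, dtype=bool) | True,
                             covariates=cov)
        out = covariate_scan(cohort, "second")
        assert len(out) == 2
        for _, row in out.iterrows():
            rho, p = spearman_tied(cov[row["covariate"]], cohort.outcome)
            assert row["rho"] == pytest.approx(rho)
            assert row["p"] == pytest.approx(p)
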