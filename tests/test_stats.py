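"""Matched-pair statistics: enumeration oracles and cross-library checks."""

import numpy as np
import pytest
from scipy import stats as sps

from omentex import (
    bonferroni_adjust,
    clogit_fit,
    fisher_exact_2x2,
    gen_feature_table,
    univariate_table,
    wilcoxon_signed_rank,
)
from omentex.simulate import SimConfig
from omentex.stats import clogit_from_differences, pair_differences

from conftest import brute_fisher_two_sided, brute_wilcoxon_two_sided, grid_clogit_1d


class TestWilcoxonSignedRank:
    def test_all_positive_differences_small_n(self):
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert res.statistic == 6.0  # maximal positive rank sum
        assert res.p_value == pytest.approx(0.25)  # 2 * P(W+ >= 6) = 2/8

    def test_perfectly_symmetric_differences(self):
        res = wilcoxon_signed_rank([5, 0], [0, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.p_value == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1])

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        # integer differences force ties and some zeros
        case = rng.integers(0, 6, n).astype(float)
        control = rng.integers(0, 6, n).astype(float)
        if (case == control).all():
            case[0] += 1
        res = wilcoxon_signed_rank(case, control)
        assert res.p_value == pytest.approx(brute_wilcoxon_two_sided(case - control), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(5):
            case = rng.normal(0, 1, 12)
            control = rng.normal(0, 1, 12)
            ours = wilcoxon_signed_rank(case, control)
            ref = sps.wilcoxon(case, control, zero_method="wilcox", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        # n = 15 sits on the exact/approximate boundary; the two paths agree to ~0.02
        for _ in range(10):
            case = rng.normal(0.3, 1, 16)
            control = rng.normal(0, 1, 16)
            approx = wilcoxon_signed_rank(case, control)  # n=16 -> normal path
            ref = sps.wilcoxon(case, control, zero_method="wilcox", method="exact")
            assert approx.p_value == pytest.approx(ref.pvalue, abs=0.02)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[10, 10], [31, 31]], 1.0),  # balanced ascites split, 41 + 41
            ([[3, 2], [7, 8]], 1.0),  # balanced split at validation size
            ([[5, 0], [0, 5]], 2 / 252),  # both extreme tables of C(10,5)
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(table).p_value == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_full_enumeration_small_totals(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, (2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        ours = fisher_exact_2x2(t).p_value
        assert ours == pytest.approx(brute_fisher_two_sided(t.tolist()), rel=1e-9)
        ref = sps.fisher_exact(t).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestBonferroni:
    def test_values(self):
        assert bonferroni_adjust(0.05, 12) == pytest.approx(0.0041667, abs=1e-6)
        assert bonferroni_adjust(0.05, 1) == 0.05
        assert bonferroni_adjust(0.05, 5) == pytest.approx(0.01)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.05, 0)


class TestConditionalLogit:
    def test_one_covariate_matches_grid_likelihood_maximizer(self):
        d = np.array([1.0, 1.0, -1.0])
        fit = clogit_from_differences(d, ["x"])
        assert fit.converged
        assert fit.coef[0] == pytest.approx(grid_clogit_1d(d), abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_one_covariate_toys(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, 15)
        fit = clogit_from_differences(d, ["x"])
        assert fit.converged
        assert fit.coef[0] == pytest.approx(grid_clogit_1d(d), abs=1e-4)

    def test_zero_difference_covariate_flagged(self):
        D = np.column_stack([np.zeros(5), np.array([1.0, -1, 1, 1, -1])])
        fit = clogit_from_differences(D, ["flat", "x"])
        assert fit.coef[0] == 0.0 and np.isinf(fit.se[0])
        assert "flat" in fit.zero_information
        assert np.isfinite(fit.coef[1])

    def test_monotone_likelihood_detected_as_separation(self):
        fit = clogit_from_differences(np.array([0.5, 1.0, 2.0]), ["x"])
        assert fit.separation_detected and not fit.converged
        assert np.isnan(fit.coef).all()

    def test_matches_statsmodels_conditional_logit(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        n = 40
        D = rng.normal(0.2, 1.0, (n, 2))
        fit = clogit_from_differences(D, ["a", "b"])
        # build the explicit matched-pair layout for statsmodels
        X = np.vstack([D, np.zeros_like(D)])
        y = np.r_[np.ones(n), np.zeros(n)]
        groups = np.r_[np.arange(n), np.arange(n)]
        ref = ConditionalLogit(y, X, groups=groups).fit(method="newton", tol=1e-10, disp=False)
        assert fit.coef == pytest.approx(ref.params, abs=1e-5)
        assert fit.se == pytest.approx(ref.bse, rel=1e-3)

    def test_parameter_scale_invariance_of_fit(self, rng):
        # conditional-likelihood form == difference-logistic form; rescaling a
        # covariate rescales its coefficient exactly
        D = rng.normal(0.1, 1.0, (30, 1))
        f1 = clogit_from_differences(D, ["x"])
        f2 = clogit_from_differences(D * 10, ["x"])
        assert f1.coef[0] == pytest.approx(f2.coef[0] * 10, rel=1e-6)


@pytest.fixture(scope="module")
def cohort():
    test, _ = gen_feature_table(SimConfig(seed=101, n_pairs_test=41))
    return test


class TestUnivariateTable:
    def test_structure_and_flags(self, cohort):
        tbl = univariate_table(cohort)
        assert len(tbl) == 12  # 5 clinical + 7 texture comparisons
        assert np.allclose(tbl["adjusted_alpha"], 0.05 / 12)
        assert ((tbl["p_value"] >= 0) & (tbl["p_value"] <= 1)).all()
        assert (tbl["significant"] == (tbl["p_value"] < 0.05 / 12)).all()

    def test_interpolated_quartiles(self):
        q = np.quantile([1, 2, 3, 4], [0.25, 0.5, 0.75])
        tbl_med = np.quantile([1, 2, 3, 4], 0.5)
        assert tbl_med == pytest.approx(2.5)
        assert q[0] == pytest.approx(1.75) and q[2] == pytest.approx(3.25)

    def test_forced_entropy_shift_gives_minimal_p(self, cohort):
        df = cohort.copy()
        occ = df["group"] == "occult"
        base = df.loc[~occ, "entropy"].to_numpy()
        df.loc[~occ, "entropy"] = base
        df.loc[occ, "entropy"] = (
            df.loc[~occ, "entropy"].to_numpy() + 0.5
        )  # every within-pair difference positive
        tbl = univariate_table(df).set_index("variable")
        p_entropy = tbl.loc["entropy", "p_value"]
        # all-positive differences at n=41: smallest attainable two-sided p
        assert p_entropy < 1e-7
        assert tbl.loc["entropy", "significant"]

    def test_missing_column_raises_by_name(self, cohort):
        with pytest.raises(KeyError, match="entropy"):
            univariate_table(cohort.drop(columns=["entropy"]))


class TestPairDifferences:
    def test_missing_pairs_dropped(self):
        test, _ = gen_feature_table(SimConfig(seed=3, n_pairs_test=5))
        test.loc[test.index[0], "entropy"] = np.nan
        D, n_used = pair_differences(test, ["entropy"])
        assert n_used == 4 and D.shape == (4, 1)

    def test_clogit_fit_on_cohort(self):
        test, _ = gen_feature_table(SimConfig(seed=9, n_pairs_test=41), effect={"entropy": 0.1})
        fit = clogit_fit(test, ["entropy"])
        assert fit.n_pairs_used == 41
        assert fit.converged or fit.separation_detected
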