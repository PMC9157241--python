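import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acetrend.quant import (
    DISPERSION_FLOOR,
    base_mean,
    estimate_dispersion,
    fpkm,
    nb_exact_pvalue,
    nb_test,
    size_factors,
)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, make_matrix):
        cm = make_matrix({"a": [10, 100, 7], "b": [10, 100, 7]})
        assert np.allclose(size_factors(cm), 1.0)

    def test_hand_median_of_ratios(self, make_matrix):
        # 2 genes x 2 samples: geometric means (sqrt(200), sqrt(20000));
        # each column's ratios are constant -> factors 1/sqrt(2), sqrt(2)
        cm = make_matrix({"a": [10, 100], "b": [20, 200]})
        f = size_factors(cm)
        assert f["a"] == pytest.approx(1 / math.sqrt(2), rel=1e-12)
        assert f["b"] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_scale_equivariance_of_factor_ratios(self, make_matrix):
        # scaling one column by c multiplies its factor by c relative to the
        # others (the absolute factors all shift by c^(-1/n) because the
        # geometric-mean reference includes the scaled column)
        cm = make_matrix({"a": [10, 100, 55], "b": [20, 150, 44], "c": [5, 80, 60]})
        f0 = size_factors(cm)
        scaled = cm.counts.copy()
        scaled["b"] = scaled["b"] * 3
        cm2 = make_matrix({k: scaled[k].tolist() for k in scaled.columns})
        f1 = size_factors(cm2)
        assert f1["b"] / f1["a"] == pytest.approx(3 * f0["b"] / f0["a"], rel=1e-12)
        assert f1["c"] / f1["a"] == pytest.approx(f0["c"] / f0["a"], rel=1e-12)
        # every factor shifts by the same c^(-1/n)
        assert f1["a"] / f0["a"] == pytest.approx(3 ** (-1 / 3), rel=1e-12)

    def test_zero_in_every_gene_is_an_error(self, make_matrix):
        cm = make_matrix({"a": [0, 10], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive counts"):
            size_factors(cm)


class TestFpkm:
    def test_unit_plug_in(self, make_matrix):
        # count 10, length 1000 bp, column total 1e6 -> FPKM 10
        cm = make_matrix({"s": [10, 10**6 - 10]}, lengths=[1000, 5000])
        assert fpkm(cm).loc["g0", "s"] == pytest.approx(10.0)

    def test_formula_evaluation(self, make_matrix):
        # count 50, length 2500 bp, total 2e6 -> FPKM 10
        cm = make_matrix({"s": [50, 2 * 10**6 - 50]}, lengths=[2500, 1000])
        assert fpkm(cm).loc["g0", "s"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self, make_matrix):
        cm = make_matrix({"s": [0, 100]}, lengths=[123, 999])
        assert fpkm(cm).loc["g0", "s"] == 0.0

    def test_depth_invariance(self, make_matrix):
        cm1 = make_matrix({"s": [10, 30, 60]})
        cm2 = make_matrix({"s": [20, 60, 120]})
        assert np.allclose(fpkm(cm1)["s"], fpkm(cm2)["s"])

    def test_zero_column_sum_names_sample(self, make_matrix):
        cm = make_matrix({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            fpkm(cm)


class TestEstimateDispersion:
    def test_moment_oracle(self, make_matrix):
        # one group [80, 100, 120]: mean 100, var 400 -> alpha = 300/1e4
        cm = make_matrix({"a": [80], "b": [100], "c": [120]})
        f = pd.Series(1.0, index=["a", "b", "c"])
        alpha = estimate_dispersion(cm, f, [["a", "b", "c"]])
        assert alpha["g0"] == pytest.approx((400 - 100) / 100**2)

    def test_variance_at_or_below_mean_floors(self, make_matrix):
        # [90, 100, 110]: var 100 == mean 100 -> floored
        cm = make_matrix({"a": [90], "b": [100], "c": [110]})
        f = pd.Series(1.0, index=["a", "b", "c"])
        assert estimate_dispersion(cm, f, [["a", "b", "c"]])["g0"] == DISPERSION_FLOOR

    def test_constant_gene_floors(self, make_matrix):
        cm = make_matrix({"a": [50], "b": [50], "c": [50]})
        f = pd.Series(1.0, index=["a", "b", "c"])
        assert estimate_dispersion(cm, f, [["a", "b", "c"]])["g0"] == DISPERSION_FLOOR

    def test_no_replicates_falls_back_to_default(self, make_matrix):
        cm = make_matrix({"a": [50], "b": [70]})
        f = pd.Series(1.0, index=["a", "b"])
        alpha = estimate_dispersion(cm, f, [["a"], ["b"]])
        assert (alpha == 0.1).all()


def _enumeration_pvalue(k_a, k_b, mu_a, mu_b, var_a, var_b):
    """Independent oracle: direct scipy pmf enumeration in linear space."""

    def pmf(x, mu, var):
        if var <= mu:
            return stats.poisson.pmf(x, mu)
        size = mu**2 / (var - mu)
        return stats.nbinom.pmf(x, size, size / (size + mu))

    ks = k_a + k_b
    probs = np.array([pmf(a, mu_a, var_a) * pmf(ks - a, mu_b, var_b) for a in range(ks + 1)])
    obs = probs[k_a]
    return probs[probs <= obs * (1 + 1e-7)].sum() / probs.sum()


class TestNbExactTest:
    def test_enumeration_oracle_extreme_split(self):
        """K_A=0, K_B=10, equal groups, alpha=0.1: matches 11-term enumeration."""
        q = 5.0  # pooled mean with one sample per group, factors 1
        mu, var = q, q + 0.1 * q * q
        p = nb_exact_pvalue(0, 10, mu, mu, var, var)
        assert p == pytest.approx(_enumeration_pvalue(0, 10, mu, mu, var, var), rel=1e-10)

    @pytest.mark.parametrize("k_a,k_b,alpha", [(3, 12, 0.05), (7, 7, 0.2), (0, 25, 0.0)])
    def test_enumeration_oracle_various(self, k_a, k_b, alpha):
        q = (k_a + k_b) / 2
        mu, var = q, q + alpha * q * q
        p = nb_exact_pvalue(k_a, k_b, mu, mu, var, var)
        assert p == pytest.approx(
            _enumeration_pvalue(k_a, k_b, mu, mu, var, var), rel=1e-10
        )

    def test_identical_groups_symmetric(self, make_matrix, two_group_design, injury_window):
        design = two_group_design(2)
        ids = design.sample_ids()
        cm = make_matrix({s: [40, 7] for s in ids})
        f = pd.Series(1.0, index=ids)
        res = nb_test(cm, f, injury_window, 0.1, design)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_swap_antisymmetry(self, make_matrix, two_group_design, injury_window):
        design = two_group_design(2)
        a_ids = design.sample_ids(timepoint="N")
        b_ids = design.sample_ids(timepoint="C1d")
        cm_fwd = make_matrix(
            {**{s: [10, 100] for s in a_ids}, **{s: [40, 90] for s in b_ids}}
        )
        cm_rev = make_matrix(
            {**{s: [40, 90] for s in a_ids}, **{s: [10, 100] for s in b_ids}}
        )
        f = pd.Series(1.0, index=design.sample_ids())
        fwd = nb_test(cm_fwd, f, injury_window, 0.05, design)
        rev = nb_test(cm_rev, f, injury_window, 0.05, design)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)

    def test_poisson_limit_matches_conditioned_binomial(self):
        """alpha=0 equals the exact binomial split test on small totals."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            ks = int(rng.integers(1, 31))
            k_a = int(rng.integers(0, ks + 1))
            mu_a = float(rng.uniform(0.5, 10))
            mu_b = float(rng.uniform(0.5, 10))
            p = nb_exact_pvalue(k_a, ks - k_a, mu_a, mu_b, mu_a, mu_b)
            # oracle: X | K_S ~ Binomial(K_S, mu_a / (mu_a + mu_b))
            pm = stats.binom.pmf(np.arange(ks + 1), ks, mu_a / (mu_a + mu_b))
            oracle = pm[pm <= pm[k_a] * (1 + 1e-7)].sum()
            assert p == pytest.approx(oracle, abs=1e-6)

    def test_all_zero_gene_p_one(self, make_matrix, two_group_design, injury_window):
        design = two_group_design(2)
        ids = design.sample_ids()
        cm = make_matrix({s: [0, 10] for s in ids})
        f = pd.Series(1.0, index=ids)
        res = nb_test(cm, f, injury_window, 0.1, design)
        assert res.loc[res["gene_id"] == "g0", "p_value"].iloc[0] == 1.0
        assert res.loc[res["gene_id"] == "g0", "log2fc"].iloc[0] == 0.0


class TestBaseMean:
    def test_two_sample_mean(self, make_matrix, two_group_design, injury_window):
        design = two_group_design(1)
        ids = design.sample_ids()
        cm = make_matrix({ids[0]: [10], ids[1]: [30]})
        f = pd.Series(1.0, index=ids)
        bm = base_mean(cm, f, injury_window, design)
        assert bm["g0"] == pytest.approx(20.0)

    def test_hand_mean_with_replicates(self, make_matrix, two_group_design, injury_window):
        design = two_group_design(3)
        ids = design.sample_ids()
        vals = [12, 18, 24, 30, 36, 42]
        cm = make_matrix({s: [v] for s, v in zip(ids, vals)})
        f = pd.Series([1.0, 1.5, 2.0, 1.0, 1.5, 2.0], index=ids)
        bm = base_mean(cm, f, injury_window, design)
        expected = np.mean([v / fac for v, fac in zip(vals, f)])
        assert bm["g0"] == pytest.approx(expected, rel=1e-12)
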