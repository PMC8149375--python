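"""Size factors, NB interaction LRT, intensity F-test, BH and ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synscreen.errors import SchemaError
from synscreen.interaction import (bh_adjust, fit_interaction_glm,
                                   intensity_interaction, lrt_interaction,
                                   preprocess_intensities,
                                   rank_by_interaction, size_factors)
from synscreen.simulate import CountSimConfig, simulate_counts


def make_design(n_reps=3):
    arms = [(0, 0), (1, 0), (0, 1), (1, 1)]
    rows = [(f"s{k}", xd, xc) for k, (xd, xc) in
            enumerate(a for a in arms for _ in range(n_reps))]
    df = pd.DataFrame(rows, columns=["sample", "x_d", "x_c"]).set_index("sample")
    df["x_dc"] = df["x_d"] * df["x_c"]
    return df


class TestSizeFactors:
    def test_doubled_sample(self):
        c = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        sf = size_factors(c)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_unit_factors(self):
        c = pd.DataFrame({"a": [5, 9, 3], "b": [5, 9, 3], "c": [5, 9, 3]})
        np.testing.assert_allclose(size_factors(c), 1.0)

    def test_simulated_factors_recovered(self):
        counts, design, _ = simulate_counts(
            CountSimConfig(n_genes=2000, frac_interaction=0.0, seed=11))
        sf = size_factors(counts)
        true = design.attrs["size_factors"]
        np.testing.assert_allclose(sf.to_numpy(), true.to_numpy(), rtol=0.05)

    def test_fallback_on_no_common_gene(self):
        c = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(UserWarning, match="library-size"):
            sf = size_factors(c)
        np.testing.assert_allclose(sf, 1.0)


class TestInteractionGLM:
    def test_exact_log2_means(self):
        """Noise-free means 2^(5 + x_d): beta_d = 1, beta_dc = 0."""
        design = make_design(2)
        y = 2.0 ** (5 + design["x_d"].to_numpy())
        fit = fit_interaction_glm(y, design, dispersion=0.05)
        assert fit["converged"]
        assert fit["beta_d"] == pytest.approx(1.0, abs=1e-5)
        assert fit["beta_dc"] == pytest.approx(0.0, abs=1e-5)
        assert 2 * (fit["ll_full"] - fit["ll_reduced"]) == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_feature_flagged(self):
        fit = fit_interaction_glm(np.zeros(12), make_design(3), 0.05)
        assert not fit["converged"] and np.isnan(fit["beta_dc"])

    def test_planted_coefficient_recovery(self):
        """Mean estimate of a planted log2 interaction of 1.0 is unbiased
        within 0.1 across 500 planted genes."""
        counts, design, truth = simulate_counts(CountSimConfig(
            n_genes=2000, n_reps=3, frac_interaction=0.25,
            beta_dc_magnitude=1.0, dispersion=0.05, seed=6))
        res = lrt_interaction(counts, design, dispersion=0.05)
        planted = truth["has_interaction"]
        assert planted.sum() == 500
        bias = (res["beta_dc"] - truth["beta_dc"])[planted].mean()
        assert abs(bias) < 0.1


class TestLRT:
    def test_statistic_nonnegative_and_null_zero(self):
        design = make_design(2)
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(100, size=(30, len(design))),
            index=[f"g{i}" for i in range(30)], columns=design.index)
        res = lrt_interaction(counts, design, dispersion=0.05)
        assert (res["lrt_statistic"].dropna() >= 0).all()

    def test_constant_interaction_column_gives_p_one(self):
        """If x_dc is all zero the models coincide: LRT 0, p 1."""
        design = make_design(2)
        design["x_dc"] = 0
        y = np.random.default_rng(1).poisson(50, len(design)).astype(float)
        fit_full = fit_interaction_glm(y, design, 0.05)
        # full and reduced describe the same mean space; LRT collapses
        lrt = 2 * (fit_full["ll_full"] - fit_full["ll_reduced"])
        assert lrt == pytest.approx(0.0, abs=1e-6)

    def test_unpopulated_cell_rejected(self):
        design = make_design(2)
        design = design[~((design["x_d"] == 1) & (design["x_c"] == 1))]
        counts = pd.DataFrame(np.ones((3, len(design))),
                              index=list("abc"), columns=design.index)
        with pytest.raises(SchemaError, match=r"\(1, 1\)"):
            lrt_interaction(counts, design)

    def test_scaling_one_sample_absorbed_by_size_factors(self):
        counts, design, _ = simulate_counts(
            CountSimConfig(n_genes=300, frac_interaction=0.1, seed=12))
        res0 = lrt_interaction(counts, design, dispersion=0.05)
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 2).astype(int)
        res1 = lrt_interaction(scaled, design, dispersion=0.05)
        diff = (res0["beta_dc"] - res1["beta_dc"]).abs()
        # not an exact invariance: rescaled integer counts re-weight the NB
        # likelihood slightly, so agreement is statistical, not bitwise
        assert diff.median() < 0.02
        assert diff.max() < 0.3


class TestIntensityInteraction:
    def test_additive_data_gives_f_zero(self):
        design = make_design(2)
        y = 1.0 + 0.5 * design["x_d"] + 0.2 * design["x_c"]
        tab = pd.DataFrame([y.to_numpy()], index=["p1"], columns=design.index)
        res = intensity_interaction(tab, design)
        assert res.loc["p1", "f_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["p1", "p_value"] == pytest.approx(1.0)

    def test_planted_shift_power_matches_noncentral_f_oracle(self, rng):
        """Empirical detection rate of a planted 1.0 log10-unit interaction
        shift (sd 0.2, n = 2 per arm) equals the closed-form noncentral-F
        power of the nested test."""
        design = make_design(2)
        X = np.column_stack([np.ones(len(design)),
                             design[["x_d", "x_c", "x_dc"]].to_numpy(float)])
        c_var = np.linalg.inv(X.T @ X)[3, 3]
        sigma, shift, df_resid = 0.2, 1.0, len(design) - 4
        ncp = shift ** 2 / (sigma ** 2 * c_var)
        fcrit = stats.f.isf(0.05, 1, df_resid)
        analytic_power = stats.ncf.sf(fcrit, 1, df_resid, ncp)

        n_planted = 2000
        data = rng.normal(0, sigma, size=(n_planted, len(design)))
        data += shift * design["x_dc"].to_numpy()[None, :]
        tab = pd.DataFrame(data, index=[f"p{i}" for i in range(n_planted)],
                           columns=design.index)
        res = intensity_interaction(tab, design)
        empirical = float((res["p_value"] < 0.05).mean())
        assert empirical == pytest.approx(analytic_power, abs=0.03)

    def test_null_p_values_uniform(self, rng):
        design = make_design(2)
        data = rng.normal(0, 1, size=(2000, len(design)))
        tab = pd.DataFrame(data, index=[f"p{i}" for i in range(2000)],
                           columns=design.index)
        res = intensity_interaction(tab, design)
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestBH:
    def test_matches_brute_force_step_up(self, rng):
        """Exhaustive comparison with a literal BH step-up on short vectors."""
        def brute_bh(p):
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(n)
            prev = 1.0
            for rank_from_end, idx in enumerate(order[::-1]):
                rank = n - rank_from_end
                prev = min(prev, p[idx] * n / rank)
                q[idx] = prev
            return q

        for n in range(1, 21):
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(bh_adjust(p), brute_bh(p), atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRanking:
    def test_signed_order_and_ties(self):
        res = pd.DataFrame({"beta_dc": [2.0, -1.0, 0.0]},
                           index=["first", "second", "third"])
        ranked = rank_by_interaction(res)
        assert list(ranked.index) == ["first", "third", "second"]
        res_tied = pd.DataFrame({"beta_dc": [1.0, 1.0, 1.0]},
                                index=["c", "a", "b"])
        assert list(rank_by_interaction(res_tied).index) == ["a", "b", "c"]


class TestPreprocess:
    def test_impute_and_quantile_normalize(self):
        raw = pd.DataFrame({"s1": [10.0, 100.0, np.nan],
                            "s2": [20.0, np.nan, 1000.0],
                            "s3": [15.0, 90.0, 1100.0]},
                           index=["a", "b", "c"])
        out = preprocess_intensities(raw)
        assert out.notna().all().all()
        # identical distributions across samples after normalization
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
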