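"""Size factors, NB Wald test, BH adjustment, and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starr_regvar import bh_adjust, classify_elements, nb_wald_lfc, size_factors_median_of_ratios
from starr_regvar.activity_calling import call_activity


def _design(cols):
    return {c: ("output" if str(c).startswith("out") else "input") for c in cols}


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"input_rep1": [10, 50, 100], "output_rep1": [10, 50, 100]})
        sf = size_factors_median_of_ratios(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_hand_computed_example(self):
        counts = pd.DataFrame([[10, 20], [100, 200], [50, 100]], columns=["a", "b"])
        sf = size_factors_median_of_ratios(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one library by c multiplies its factor relative to every
        other library by c (factors are defined up to a common constant:
        the scaled column also shifts the per-row geometric means)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (50, 4)) + 1, columns=list("abcd"))
        sf = size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        sf2 = size_factors_median_of_ratios(scaled)
        assert np.isclose(sf2["b"] / sf2["a"], 3 * sf["b"] / sf["a"])
        ratios = (sf2 / sf).to_numpy()
        assert np.allclose(ratios[[0, 2, 3]], ratios[0])  # others move together

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(80, (40, 3)) + 1)
        sf = size_factors_median_of_ratios(counts)
        sf2 = size_factors_median_of_ratios(counts.sample(frac=1, random_state=2))
        assert np.allclose(sf, sf2)

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(pd.DataFrame({"a": [0, 0], "b": [1, 0]}))


class TestNbWald:
    def test_null_symmetry_identical_counts(self):
        counts = pd.DataFrame(
            {"input_rep1": [500] * 5, "input_rep2": [500] * 5,
             "output_rep1": [500] * 5, "output_rep2": [500] * 5}
        )
        sf = size_factors_median_of_ratios(counts)
        res = nb_wald_lfc(counts, sf, _design(counts.columns), dispersion=0.01)
        assert (res["log2FC"].abs() < 0.05).all()
        assert (res["pvalue"] > 0.5).all()

    def test_poisson_limit_matches_glm_oracle(self):
        """dispersion -> 0: estimates agree with a Poisson log-linear GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            {"input_rep1": rng.poisson(200, 20), "input_rep2": rng.poisson(200, 20),
             "output_rep1": rng.poisson(300, 20), "output_rep2": rng.poisson(300, 20)}
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_lfc(counts, sf, _design(counts.columns), dispersion=1e-10)
        X = sm.add_constant(np.array([0, 0, 1, 1.0]))
        for i in range(len(counts)):
            y = counts.iloc[i].to_numpy()
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            lfc_oracle = fit.params[1] / np.log(2)
            z_oracle = fit.params[1] / fit.bse[1]
            p_oracle = 2 * stats.norm.sf(abs(z_oracle))
            assert np.isclose(res["log2FC"].iloc[i], lfc_oracle, rtol=1e-3)
            assert np.isclose(res["pvalue"].iloc[i], p_oracle, rtol=1e-2, atol=1e-12)

    def test_monte_carlo_recovery_of_planted_lfc(self):
        """Planted log2FC=1 at depth 500, dispersion 0.01 over 200 regions:
        the estimator is unbiased and its spread matches the delta-method
        oracle sd(log2FC) = sqrt((1/mu_in + a)/2 + (1/mu_out + a)/2)/ln2."""
        rng = np.random.default_rng(17)
        n, alpha = 200, 0.01
        r = 1 / alpha

        def nb(mean, size):
            return rng.negative_binomial(r, r / (r + mean), size=size)

        counts = pd.DataFrame(
            {"input_rep1": nb(500, n), "input_rep2": nb(500, n),
             "output_rep1": nb(1000, n), "output_rep2": nb(1000, n)}
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_lfc(counts, sf, _design(counts.columns), dispersion=alpha)
        sd_oracle = np.sqrt((1 / 500 + alpha) / 2 + (1 / 1000 + alpha) / 2) / np.log(2)
        assert res["log2FC"].mean() == pytest.approx(1.0, abs=3 * sd_oracle / np.sqrt(n))
        assert res["log2FC"].std() == pytest.approx(sd_oracle, rel=0.2)
        # coverage at +/-2 oracle sd behaves like a normal error
        assert (np.abs(res["log2FC"] - 1.0) < 2 * sd_oracle).mean() >= 0.9

    def test_all_zero_region_reported_missing(self):
        counts = pd.DataFrame(
            {"input_rep1": [0, 100], "input_rep2": [0, 120],
             "output_rep1": [0, 90], "output_rep2": [0, 110]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_lfc(counts, sf, _design(counts.columns))
        assert np.isnan(res["pvalue"].iloc[0]) and np.isnan(res["log2FC"].iloc[0])
        assert np.isfinite(res["pvalue"].iloc[1])

    def test_null_pvalues_approximately_uniform(self, null_screen):
        _, screen = null_screen
        counts = screen.region_counts
        sf = size_factors_median_of_ratios(counts)
        res = nb_wald_lfc(counts, sf, _design(counts.columns))
        p = res["pvalue"].dropna()
        assert stats.kstest(p, "uniform").statistic < 0.06


class TestBH:
    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_ties_all_equal(self):
        assert np.allclose(bh_adjust([0.07] * 5), 0.07)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestClassification:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["baseMean", "log2FC", "pvalue"])

    def test_sign_and_threshold_rules(self):
        res = self._results([
            (100, 1.0, 1e-5),    # -> PRE
            (100, -1.0, 1e-5),   # -> NRE
            (100, 2.0, 0.5),     # -> inactive
            (2, 3.0, 1e-9),      # below min_base_mean -> filtered
        ])
        out = classify_elements(res, fdr_alpha=0.01, min_base_mean=10)
        assert list(out["class"]) == ["PRE", "NRE", "inactive", "filtered"]
        assert np.isnan(out["padj"].iloc[3])

    def test_filtered_regions_excluded_from_bh_family(self):
        res = self._results([(100, 1.0, 0.03), (2, 1.0, 0.001), (100, 1.0, 0.04)])
        out = classify_elements(res, fdr_alpha=0.05, min_base_mean=10)
        # BH over the two testable regions only: padj = [0.045 (0.03*2/... ), ...]
        assert np.allclose(out["padj"].iloc[[0, 2]], [0.04 * 2 / 2, 0.04])
        assert out["class"].iloc[1] == "filtered"

    def test_padj_at_least_p(self, small_screen):
        _, screen = small_screen
        act = call_activity(screen.region_counts, _design(screen.region_counts.columns))
        ok = act["padj"].notna()
        assert (act.loc[ok, "padj"] >= act.loc[ok, "pvalue"] - 1e-12).all()


def test_recovery_with_correct_sign_on_screen(small_screen):
    """Planted strong activities are recalled with the right sign."""
    _, screen = small_screen
    act = call_activity(screen.region_counts, _design(screen.region_counts.columns))
    m = act.join(screen.truth, rsuffix="_t")
    strong = m[np.abs(m["log2fc"]) >= 1]
    correct = ((strong["class"] == "PRE") & (strong["log2fc"] > 0)) | (
        (strong["class"] == "NRE") & (strong["log2fc"] < 0)
    )
    assert correct.mean() >= 0.9
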