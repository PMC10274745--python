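"""Unit and property tests for the NB dosage-model machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import xydosage as xd
from xydosage.dosage import _irls_nb


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

class TestComputeTpm:
    def test_equal_length_normalized_rates(self):
        counts = pd.DataFrame({"s1": [100, 200]}, index=pd.Index(["gA", "gB"], name="gene_id"))
        ann = pd.DataFrame({"effective_length": [1000, 2000]}, index=counts.index)
        tpm = xd.compute_tpm(counts, ann)
        np.testing.assert_allclose(tpm["s1"], [500000.0, 500000.0])

    def test_single_gene_gets_everything(self):
        counts = pd.DataFrame({"s1": [7]}, index=pd.Index(["gA"], name="gene_id"))
        ann = pd.DataFrame({"effective_length": [500]}, index=counts.index)
        assert float(xd.compute_tpm(counts, ann).iloc[0, 0]) == pytest.approx(1e6)

    def test_matches_direct_formula_and_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(5, 3)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(3)],
        )
        lengths = pd.Series(rng.integers(200, 3000, size=5), index=counts.index)
        ann = pd.DataFrame({"effective_length": lengths})
        tpm = xd.compute_tpm(counts, ann)
        for s in counts.columns:
            rate = counts[s] / lengths
            np.testing.assert_allclose(tpm[s], 1e6 * rate / rate.sum())
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)

    def test_zero_sample_names_the_sample(self):
        counts = pd.DataFrame({"good": [10], "empty": [0]}, index=pd.Index(["gA"]))
        ann = pd.DataFrame({"effective_length": [100]}, index=counts.index)
        with pytest.raises(ValueError, match="empty"):
            xd.compute_tpm(counts, ann)


# ---------------------------------------------------------------------------
# expressed-gene filter
# ---------------------------------------------------------------------------

class TestFilterExpressed:
    @staticmethod
    def _sheet(n_xx=3, n_xy=3):
        rows = [("LCL", 2, 0)] * n_xx + [("LCL", 1, 1)] * n_xy
        return pd.DataFrame(
            rows, columns=["cell_type", "x_copies", "y_copies"],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_median_exactly_at_threshold_is_retained(self):
        samples = self._sheet()
        tpm = pd.DataFrame(1.0, index=["g0"], columns=samples.index)
        assert "g0" in xd.filter_expressed(tpm, samples)["LCL"]

    def test_all_zero_gene_excluded(self):
        samples = self._sheet()
        tpm = pd.DataFrame(0.0, index=["g0"], columns=samples.index)
        assert len(xd.filter_expressed(tpm, samples)["LCL"]) == 0

    def test_planted_medians_match_per_gene_median_oracle(self, rng):
        samples = self._sheet(5, 5)
        tpm = pd.DataFrame(
            rng.uniform(0, 2.5, size=(20, 10)),
            index=[f"g{i}" for i in range(20)],
            columns=samples.index,
        )
        kept = set(xd.filter_expressed(tpm, samples)["LCL"])
        xx = samples.index[:5]
        xy = samples.index[5:]
        expected = {
            g for g in tpm.index
            if tpm.loc[g, xx].median() >= 1 or tpm.loc[g, xy].median() >= 1
        }
        assert kept == expected

    def test_no_euploid_samples_is_an_error(self):
        samples = pd.DataFrame(
            {"cell_type": ["LCL"], "x_copies": [3], "y_copies": [0]}, index=["s0"]
        )
        tpm = pd.DataFrame(1.0, index=["g0"], columns=["s0"])
        with pytest.raises(ValueError, match="euploid"):
            xd.filter_expressed(tpm, samples)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_uniform_double_depth(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["a", "b", "c"])
        sf = xd.compute_size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 9], "s2": [5, 9], "s3": [5, 9]}, index=["a", "b"])
        np.testing.assert_allclose(xd.compute_size_factors(counts), 1.0)

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        sf = xd.compute_size_factors(counts)
        arr = counts.to_numpy(float)
        ref = np.exp(np.mean(np.log(arr), axis=1))
        expected = np.median(arr / ref[:, None], axis=0)
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(sf, expected)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_genes_with_zeros_raises_unless_pseudo(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="pseudo"):
            xd.compute_size_factors(counts)
        sf = xd.compute_size_factors(counts, allow_pseudo_reference=True)
        assert np.all(sf > 0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    @staticmethod
    def _frame(y):
        counts = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(y)}).T.T
        counts.index = ["g0"]
        return counts

    def test_poisson_gene_estimates_near_zero(self, rng):
        y = rng.poisson(100, size=100)
        counts = pd.DataFrame([y], index=["g0"], columns=[f"s{i}" for i in range(100)])
        sheet = pd.DataFrame({"x": np.zeros(100)}, index=counts.columns)
        design = xd.build_design(sheet, [])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = xd.estimate_dispersion(counts, sf, design)
        assert float(alpha.iloc[0]) <= 1e-2

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(42)
        alpha_true, mu, n = 0.5, 200.0, 200
        lam = rng.gamma(1 / alpha_true, alpha_true * mu, size=n)
        y = rng.poisson(lam)
        counts = pd.DataFrame([y], index=["g0"], columns=[f"s{i}" for i in range(n)])
        sheet = pd.DataFrame(index=counts.columns)
        design = xd.build_design(sheet, [])
        alpha = xd.estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), design)
        assert 0.3 <= float(alpha.iloc[0]) <= 0.7

    def test_constant_counts_hit_the_floor(self):
        counts = pd.DataFrame([[50] * 10], index=["g0"], columns=[f"s{i}" for i in range(10)])
        sheet = pd.DataFrame(index=counts.columns)
        design = xd.build_design(sheet, [])
        alpha = xd.estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), design)
        assert float(alpha.iloc[0]) == pytest.approx(1e-8)

    def test_more_columns_than_samples_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["g0"], columns=["s0", "s1"])
        sheet = pd.DataFrame({"a": [0.0, 1.0]}, index=counts.columns)
        design = xd.build_design(sheet, ["a"])
        with pytest.raises(ValueError, match="identify"):
            xd.estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), design)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestAdjustBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(xd.adjust_bh([0.03]), [0.03])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(xd.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_nan_excluded_from_m_and_propagated(self):
        out = xd.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], xd.adjust_bh([0.01, 0.02]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_capped(self, ps):
        out = xd.adjust_bh(ps)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# the NB GLM itself
# ---------------------------------------------------------------------------

class TestFitDosageModel:
    def test_exact_log_linear_data_recovers_slope(self):
        # counts exactly 200 * 2^x for x in {1,2,3}: slope 1.0, intercept log2(200)
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        counts = pd.DataFrame(
            [(200 * 2**x).astype(int)], index=["g0"], columns=[f"s{i}" for i in range(6)]
        )
        samples = pd.DataFrame({"x_copies": x}, index=counts.columns)
        fit = xd.fit_dosage_model(
            counts,
            samples,
            ["x_copies"],
            size_factors=pd.Series(1.0, index=counts.columns),
            alpha=pd.Series(1e-8, index=counts.index),
        )
        t = fit.tables["x_copies"]
        assert float(t["log2FC"].iloc[0]) == pytest.approx(1.0, abs=1e-6)
        assert float(t["p"].iloc[0]) < 1e-10

    def test_constant_gene_has_zero_slopes(self):
        counts = pd.DataFrame([[100] * 8], index=["g0"], columns=[f"s{i}" for i in range(8)])
        samples = pd.DataFrame(
            {"x_copies": [1, 2, 3, 4, 1, 2, 3, 4], "y_copies": [0, 0, 0, 0, 1, 1, 1, 1]},
            index=counts.columns,
        )
        fit = xd.fit_dosage_model(
            counts,
            samples,
            ["x_copies", "y_copies"],
            size_factors=pd.Series(1.0, index=counts.columns),
            alpha=pd.Series(1e-8, index=counts.index),
        )
        assert float(fit.tables["x_copies"]["log2FC"].iloc[0]) == pytest.approx(0.0, abs=1e-8)
        assert float(fit.tables["y_copies"]["log2FC"].iloc[0]) == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_statsmodels_nb_glm(self, rng):
        """Independent cross-check of coefficients and SEs on one gene."""
        n = 60
        x = rng.integers(1, 5, size=n).astype(float)
        batch = rng.integers(0, 2, size=n)
        alpha = 0.1
        mu = np.exp(3.0 + 0.3 * x + 0.2 * batch)
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
        counts = pd.DataFrame([y], index=["g0"], columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame(
            {"x_copies": x, "batch": [f"b{b}" for b in batch]}, index=counts.columns
        )
        sf = pd.Series(np.exp(rng.normal(0, 0.1, n)), index=counts.columns)
        sf /= np.exp(np.mean(np.log(sf)))
        fit = xd.fit_dosage_model(
            counts, samples, ["x_copies", "batch"],
            size_factors=sf, alpha=pd.Series(alpha, index=counts.index),
        )
        X = sm.add_constant(np.column_stack([x, batch]))
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(sf.to_numpy())
        ).fit()
        t = fit.tables["x_copies"]
        assert float(t["log2FC"].iloc[0]) * np.log(2) == pytest.approx(ref.params[1], rel=1e-5)
        assert float(t["SE"].iloc[0]) * np.log(2) == pytest.approx(ref.bse[1], rel=1e-4)

    def test_estimate_maximizes_nb_loglikelihood(self, rng):
        """The IRLS solution is a local maximum of the exact NB likelihood."""
        n, alpha = 40, 0.2
        x = rng.integers(1, 4, size=n).astype(float)
        mu = np.exp(2.0 + 0.4 * x)
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu)).astype(float)
        counts = pd.DataFrame([y.astype(int)], index=["g0"], columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({"x_copies": x}, index=counts.columns)
        fit = xd.fit_dosage_model(
            counts, samples, ["x_copies"],
            size_factors=pd.Series(1.0, index=counts.columns),
            alpha=pd.Series(alpha, index=counts.index),
        )
        bhat = np.array(
            [np.nan, float(fit.tables["x_copies"]["log2FC"].iloc[0]) * np.log(2)]
        )
        X = np.column_stack([np.ones(n), x])
        # intercept on the natural scale comes from re-solving at the slope

        def loglik(b):
            m = np.exp(X @ b)
            r = 1 / alpha
            from scipy.special import gammaln

            return np.sum(
                gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                + r * np.log(r / (r + m)) + y * np.log(m / (r + m))
            )

        # profile the intercept out at the fitted slope and at perturbed slopes
        from scipy.optimize import minimize_scalar

        def profile(slope):
            res = minimize_scalar(lambda b0: -loglik(np.array([b0, slope])), bounds=(-5, 10), method="bounded")
            return -res.fun

        at_hat = profile(bhat[1])
        for eps in (1e-3, -1e-3, 0.05, -0.05):
            assert at_hat >= profile(bhat[1] + eps) - 1e-9

    def test_rank_deficient_design_names_aliased_columns(self):
        counts = pd.DataFrame([[1, 2, 3, 4]], index=["g0"], columns=list("abcd"))
        samples = pd.DataFrame(
            {"x_copies": [1.0, 2, 3, 4], "twin": [1.0, 2, 3, 4]}, index=counts.columns
        )
        with pytest.raises(ValueError, match="aliased"):
            xd.fit_dosage_model(counts, samples, ["x_copies", "twin"])

    def test_size_factor_gene_subset_barely_moves_coefficients(self, small_cohort):
        """Excluding the responsive genes from normalization mimics dropping
        sex-linked genes before computing size factors: coefficient estimates
        should be virtually identical when those genes are a small library
        fraction."""
        counts, samples, truth = small_cohort
        responsive = set(truth.responsive_x) | set(truth.responsive_y)
        rest = [g for g in counts.index if g not in responsive]
        sf_all = xd.compute_size_factors(counts, allow_pseudo_reference=True)
        sf_sub = xd.compute_size_factors(counts, gene_subset=rest, allow_pseudo_reference=True)
        fit_all = xd.fit_dosage_model(
            counts, samples, ["x_copies", "y_copies", "batch"], size_factors=sf_all
        )
        fit_sub = xd.fit_dosage_model(
            counts, samples, ["x_copies", "y_copies", "batch"], size_factors=sf_sub
        )
        for cov in ("x_copies", "y_copies"):
            diff = (fit_all.tables[cov]["log2FC"] - fit_sub.tables[cov]["log2FC"]).abs()
            assert float(diff.max()) < 0.05


class TestSaturation:
    def test_full_cohort_reproduces_full_fit_each_rep(self, small_cohort):
        counts, samples, _ = small_cohort
        sf = xd.compute_size_factors(counts, allow_pseudo_reference=True)
        full = xd.fit_dosage_model(
            counts, samples, ["x_copies", "y_copies", "batch"], size_factors=sf
        )
        n_full = {c: int((t["padj"] < 0.05).sum()) for c, t in full.tables.items()}
        table = xd.saturation_analysis(
            counts, samples, ["x_copies", "y_copies", "batch"],
            sizes=[counts.shape[1]], reps=3, seed=5,
            covariates_of_interest=["x_copies", "y_copies"],
        )
        for cov in ("x_copies", "y_copies"):
            got = table[table["covariate"] == cov]["n_significant"]
            assert (got == n_full[cov]).all()

    def test_size_below_identifiability_rejected(self, small_cohort):
        counts, samples, _ = small_cohort
        with pytest.raises(ValueError, match="minimum"):
            xd.saturation_analysis(
                counts, samples, ["x_copies", "y_copies", "batch"], sizes=[3], reps=1, seed=0
            )


def test_irls_flags_pathological_genes_instead_of_diverging():
    # a gene with a single enormous outlier still yields finite estimates
    y = np.array([[0, 0, 0, 0, 0, 100000]], dtype=float).T
    X = np.column_stack([np.ones(6), np.arange(6, dtype=float)])
    beta, se, converged = _irls_nb(y, X, np.zeros(6), np.array([0.5]))
    assert np.isfinite(beta).all() and np.isfinite(se).all()
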