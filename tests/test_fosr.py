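import numpy as np
import pandas as pd
import pytest

from catfda.fosr import (
    FoSRError,
    ModelSpec,
    PenalizedSolver,
    bootstrap_ci,
    bspline_basis,
    fit_fosr,
    significance_regions,
    standardize_covariates,
)
from catfda.grid import DEFAULT_GRID

G = DEFAULT_GRID
SPEC3 = ModelSpec(terms=("age", "bcs", "age:bcs"))


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.normal(8, 3, n),
            "bcs": np.clip(np.rint(rng.normal(6, 1, n)), 1, 9),
        }
    )


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(FoSRError):
            ModelSpec(terms=("age", "age:bcs"))

    def test_basis_dim_lower_bound(self):
        with pytest.raises(FoSRError):
            ModelSpec(basis_dim=3, penalty_order=2)

    def test_unknown_term_rejected(self):
        with pytest.raises(FoSRError):
            ModelSpec(terms=("weight",))


class TestStandardize:
    def test_closed_form_ages(self):
        cov = pd.DataFrame({"age": [4.0, 6.0, 8.0]})
        design, rec = standardize_covariates(cov, ("age",))
        np.testing.assert_allclose(design["age"], [-1.0, 0.0, 1.0])
        assert rec.means["age"] == pytest.approx(6.0)
        assert rec.sds["age"] == pytest.approx(2.0)

    def test_constant_column_rejected(self):
        cov = pd.DataFrame({"age": [4.0, 6.0], "bcs": [5.0, 5.0]})
        with pytest.raises(FoSRError, match="zero-variance"):
            standardize_covariates(cov, ("age", "bcs"))

    def test_interaction_is_product_of_standardized(self, rng):
        cov = _covariates(rng, 20)
        design, _ = standardize_covariates(cov, ("age", "bcs", "age:bcs"))
        np.testing.assert_allclose(
            design["age:bcs"], design["age"] * design["bcs"]
        )


class TestBasis:
    def test_bspline_partition_of_unity(self):
        B = bspline_basis(G.t, 15)
        assert B.shape == (288, 15)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestFitFoSR:
    def test_null_terms_estimated_near_zero(self, rng):
        n = 150
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, SPEC3.terms)
        Y = 3.0 + rng.normal(0, 0.5, (n, 288))
        fit = fit_fosr(Y, design, SPEC3)
        for term in ("age", "bcs", "age:bcs"):
            assert np.abs(fit.beta[fit.term_index(term)]).max() < 0.2

    def test_planted_sinusoid_recovered(self, rng):
        n = 150
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, SPEC3.terms)
        beta_age = np.sin(2 * np.pi * G.t / 24)
        Y = 3.0 + np.outer(design["age"], beta_age) + rng.normal(0, 0.5, (n, 288))
        fit = fit_fosr(Y, design, SPEC3)
        est = fit.beta[fit.term_index("age")]
        assert np.corrcoef(est, beta_age)[0, 1] > 0.9

    def test_zero_noise_spline_representable_interpolation_limit(self, rng):
        """Exactly-representable coefficient curves are recovered to 1e-6 as
        smoothing goes to zero."""
        n = 60
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, SPEC3.terms)
        solver = PenalizedSolver(design.to_numpy(), 15, 2, G)
        theta_true = rng.normal(size=(4, 15))
        Y = design.to_numpy() @ theta_true @ solver.B.T
        fit = fit_fosr(Y, design, SPEC3, lambdas=np.zeros(4))
        np.testing.assert_allclose(
            fit.beta, theta_true @ solver.B.T, atol=1e-6
        )

    def test_linearity_at_fixed_smoothing(self, rng):
        n = 40
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, SPEC3.terms)
        Y = rng.normal(0, 1, (n, 288))
        lam = np.full(4, 10.0)
        f1 = fit_fosr(Y, design, SPEC3, lambdas=lam)
        f2 = fit_fosr(3.0 * Y, design, SPEC3, lambdas=lam)
        np.testing.assert_allclose(f2.beta, 3.0 * f1.beta, atol=1e-10)

    def test_nested_loglik_ordering_at_fixed_smoothing(self, rng):
        n = 50
        cov = _covariates(rng, n)
        d_small, _ = standardize_covariates(cov, ("age",))
        d_big, _ = standardize_covariates(cov, ("age", "bcs"))
        Y = rng.normal(0, 1, (n, 288))
        f_small = fit_fosr(Y, d_small, ModelSpec(terms=("age",)), lambdas=np.zeros(2))
        f_big = fit_fosr(Y, d_big, ModelSpec(terms=("age", "bcs")), lambdas=np.zeros(3))
        assert f_big.loglik >= f_small.loglik - 1e-6

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((30, 2))  # duplicated intercept
        with pytest.raises(FoSRError, match="rank"):
            fit_fosr(rng.normal(size=(30, 288)), X, ModelSpec(terms=("age",)))

    def test_sigma2_positive(self, rng):
        n = 30
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, ("age",))
        fit = fit_fosr(rng.normal(0, 0.3, (n, 288)), design, ModelSpec(terms=("age",)))
        assert fit.sigma2 > 0


class TestBootstrapCI:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(12)
        n = 60
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, SPEC3.terms)
        Y = 3.0 + rng.normal(0, 0.5, (n, 288))  # all non-intercept terms null
        fit = fit_fosr(Y, design, SPEC3)
        return fit, Y, design

    def test_deterministic_given_seed(self, fitted):
        fit, Y, design = fitted
        f1 = bootstrap_ci(fit, Y, design, n_boot=50, seed=5)
        lo1, hi1 = f1.ci_lower.copy(), f1.ci_upper.copy()
        f2 = bootstrap_ci(fit, Y, design, n_boot=50, seed=5)
        np.testing.assert_array_equal(lo1, f2.ci_lower)
        np.testing.assert_array_equal(hi1, f2.ci_upper)

    def test_null_term_ci_covers_zero(self, fitted):
        fit, Y, design = fitted
        fit = bootstrap_ci(fit, Y, design, n_boot=50, seed=1)
        p = fit.term_index("age")
        covers = (fit.ci_lower[p] <= 0) & (0 <= fit.ci_upper[p])
        assert covers.mean() >= 0.80

    def test_duplicated_data_shrinks_ci_by_sqrt2(self, fitted):
        fit, Y, design = fitted
        fit = bootstrap_ci(fit, Y, design, n_boot=400, seed=2)
        p = fit.term_index("age")
        width1 = (fit.ci_upper[p] - fit.ci_lower[p]).mean()
        Y2 = np.vstack([Y, Y])
        design2 = pd.concat([design, design], ignore_index=True)
        fit2 = fit_fosr(Y2, design2, SPEC3, lambdas=fit.lambda_smooth)
        fit2 = bootstrap_ci(fit2, Y2, design2, n_boot=400, seed=2)
        width2 = (fit2.ci_upper[p] - fit2.ci_lower[p]).mean()
        assert width2 / width1 == pytest.approx(1 / np.sqrt(2), rel=0.20)

    def test_n_boot_floor(self, fitted):
        fit, Y, design = fitted
        with pytest.raises(FoSRError):
            bootstrap_ci(fit, Y, design, n_boot=10, seed=0)


class TestSignificanceRegions:
    def _fit_with_bands(self, lower, upper):
        rng = np.random.default_rng(3)
        cov = _covariates(rng, 20)
        design, _ = standardize_covariates(cov, ("age",))
        fit = fit_fosr(
            rng.normal(size=(20, 288)), design,
            ModelSpec(terms=("age",)), lambdas=np.ones(2),
        )
        fit.ci_lower = np.tile(lower, (2, 1))
        fit.ci_upper = np.tile(upper, (2, 1))
        return fit

    def test_uniformly_positive_band_spans_whole_day(self):
        fit = self._fit_with_bands(np.full(288, 0.1), np.full(288, 0.5))
        assert significance_regions(fit, "age") == [(0.0, 24.0)]

    def test_straddling_band_gives_empty_list(self):
        fit = self._fit_with_bands(np.full(288, -0.1), np.full(288, 0.1))
        assert significance_regions(fit, "age") == []

    def test_planted_morning_effect_localized(self, rng):
        n = 120
        cov = _covariates(rng, n)
        design, _ = standardize_covariates(cov, ("age",))
        bump = 0.8 * np.exp(-0.5 * ((G.t - 7.5) / 0.8) ** 2)
        Y = np.outer(design["age"], bump) + rng.normal(0, 0.3, (n, 288))
        fit = fit_fosr(Y, design, ModelSpec(terms=("age",)))
        fit = bootstrap_ci(fit, Y, design, n_boot=100, seed=4)
        regions = significance_regions(fit, "age")
        assert any(lo < 9.0 and hi > 6.0 for lo, hi in regions)

    def test_missing_bands_rejected(self, rng):
        cov = _covariates(rng, 20)
        design, _ = standardize_covariates(cov, ("age",))
        fit = fit_fosr(rng.normal(size=(20, 288)), design,
                       ModelSpec(terms=("age",)), lambdas=np.ones(2))
        with pytest.raises(FoSRError, match="bootstrap"):
            significance_regions(fit, "age")
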