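"""Unit and property tests for the robust Poisson GLM estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from robustbg import glm
from robustbg.glm import (
    DEFAULT_TUNING_CONSTANT,
    ModelSpec,
    RobustFitConfig,
    constant_background_fit,
    default_tuning_constant,
    design_matrix,
    estimator_covariance,
    fisher_consistency_correction,
    huber_psi,
    huber_weight,
    normal_efficiency,
    pearson_residual,
    robust_glm_fit,
)

C = DEFAULT_TUNING_CONSTANT


@pytest.mark.parametrize(
    "y, mu, expected",
    [(4, 4.0, 0.0), (0, 1.0, -1.0), (9, 4.0, 2.5)],
)
def test_pearson_residual_values(y, mu, expected):
    assert pearson_residual(y, mu) == pytest.approx(expected)


def test_pearson_residual_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        pearson_residual(1, 0.0)


@pytest.mark.parametrize(
    "r, c, expected",
    [(0.0, 1.345, 0.0), (0.5, 1.345, 0.5), (10.0, 1.345, 1.345), (-10.0, 1.345, -1.345)],
)
def test_huber_psi_clamps(r, c, expected):
    assert huber_psi(r, c) == pytest.approx(expected)


@pytest.mark.parametrize(
    "r, c, expected",
    [(0.0, 1.345, 1.0), (2.0, 2.0, 1.0), (4.0, 2.0, 0.5), (-4.0, 2.0, 0.5)],
)
def test_huber_weight_values(r, c, expected):
    assert huber_weight(r, c) == pytest.approx(expected)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(r=st.floats(-1e6, 1e6), c=st.floats(0.01, 100.0))
def test_huber_psi_odd_and_weight_consistent(r, c):
    assert huber_psi(-r, c) == pytest.approx(-huber_psi(r, c))
    if r != 0:
        assert huber_weight(r, c) == pytest.approx(huber_psi(r, c) / r)
    assert 0.0 < huber_weight(r, c) <= 1.0


class TestFisherConsistencyCorrection:
    def test_infinite_c_gives_zero(self):
        assert fisher_consistency_correction(3.7, math.inf) == 0.0

    def test_degenerate_small_mean(self):
        # distribution concentrated at y = 0, residual ~ -sqrt(mu) ~ 0
        assert fisher_consistency_correction(1e-9, 1.345) == pytest.approx(0.0, abs=1e-4)

    def test_matches_monte_carlo(self, rng):
        """Exact Poisson summation agrees with a 10^7-draw MC mean of psi."""
        mu = 1.0
        y = rng.poisson(mu, 10**7)
        psi = np.clip((y - mu) / math.sqrt(mu), -C, C)
        se = psi.std(ddof=1) / math.sqrt(y.size)
        exact = fisher_consistency_correction(mu, C)
        assert abs(exact - psi.mean()) < 3 * se

    def test_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            fisher_consistency_correction(-1.0, C)
        with pytest.raises(ValueError):
            fisher_consistency_correction(1.0, 0.0)


class TestNormalEfficiency:
    def test_limit_is_one(self):
        assert normal_efficiency(math.inf) == 1.0
        assert normal_efficiency(50.0) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_c(self):
        cs = [0.5, 1.0, 1.345, 2.0, 3.0]
        effs = [normal_efficiency(c) for c in cs]
        assert all(a < b for a, b in zip(effs, effs[1:]))

    def test_default_constant_solves_95_percent(self):
        c_star = default_tuning_constant(0.95)
        assert normal_efficiency(c_star) == pytest.approx(0.95, abs=1e-10)
        # the standard Huber value for 95% efficiency
        assert c_star == pytest.approx(1.345, abs=0.005)


class TestRobustFit:
    def test_constant_data_near_common_value(self):
        """A constant sample is fitted at its common value up to the small
        shift induced by the Fisher-consistency correction (a(mu) != 0
        even when every residual vanishes); at c = inf the correction
        disappears and the fit is exact."""
        fit = robust_glm_fit([3, 3, 3, 3])
        assert fit.converged
        assert fit.background == pytest.approx(3.0, rel=0.05)
        assert np.all(fit.weights == 1.0)
        exact = robust_glm_fit([3, 3, 3, 3], config=RobustFitConfig(c=math.inf))
        assert exact.background == pytest.approx(3.0, abs=1e-9)
        assert exact.beta[0] == pytest.approx(math.log(3.0), abs=1e-9)

    def test_infinite_c_is_poisson_mle(self, rng):
        y = rng.poisson(2.7, 40)
        fit = robust_glm_fit(y, config=RobustFitConfig(c=math.inf))
        assert fit.background == pytest.approx(y.mean(), abs=1e-8)

    def test_outlier_sample_matches_score_root(self):
        """The IRLS solution equals brute-force root finding of the 1-D
        robust score equation, resists the single 50-count outlier, and
        sits near the clean-background level of 1."""
        y = np.array([1, 0, 2, 1, 0, 1, 1, 2, 0, 1, 1, 0,
                      2, 1, 1, 0, 1, 2, 1, 0, 1, 1, 50, 1])

        def score(mu):
            r = (y - mu) / math.sqrt(mu)
            a = fisher_consistency_correction(mu, C)
            return float(np.clip(r, -C, C).sum()) - y.size * a

        root = optimize.brentq(score, 1e-6, 49.0, xtol=1e-12)
        fit = robust_glm_fit(y)
        assert fit.converged
        assert fit.background == pytest.approx(root, abs=1e-6)
        se = math.sqrt(fit.covariance[0, 0])
        assert abs(math.log(fit.background) - 0.0) < 3 * se  # near log(1)
        assert fit.background < y.mean()

    def test_bounded_influence_vs_mean(self, rng):
        """One wild pixel moves the robust estimate by a bounded amount
        while the sample mean diverges linearly."""
        y = rng.poisson(2.0, 25)
        base = constant_background_fit(y).background
        shifts = []
        for spike in (10**2, 10**4, 10**6):
            yy = y.copy()
            yy[0] = spike
            shifts.append(constant_background_fit(yy).background - base)
        assert shifts[2] - shifts[1] < 0.1  # influence saturates
        assert abs(shifts[2]) < 2.0
        assert (yy.mean() - y.mean()) > 10**4  # the mean does not

    def test_all_zero_input_degenerate(self):
        fit = robust_glm_fit([0, 0, 0, 0])
        assert fit.degenerate
        assert fit.background == 0.0
        assert fit.beta[0] == -math.inf
        assert fit.covariance is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            robust_glm_fit([])

    def test_nonconvergence_flagged_not_raised(self):
        fit = robust_glm_fit([0, 1, 5, 2, 1, 9], config=RobustFitConfig(max_iter=1))
        assert not fit.converged

    def test_fisher_consistency_over_replicates(self):
        """Mean of mu_hat over 10^4 replicate constant-model fits stays
        within 3 MC standard errors of the true lambda (no systematic
        bias relative to the plain mean's scale), across background
        levels from 0.1 to 10 counts/pixel."""
        rng = np.random.default_rng(42)
        n = 72  # background pixels of the default 9x9 shoebox
        for lam in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0):
            ys = rng.poisson(lam, (10_000, n))
            est = np.array([constant_background_fit(row).background for row in ys])
            se = est.std(ddof=1) / math.sqrt(est.size)
            assert abs(est.mean() - lam) < 3 * se, f"lambda={lam}"

    def test_monotone_under_background_shift(self):
        """Raising the true background raises the mean estimate (3-sigma)."""
        rng = np.random.default_rng(7)
        reps, n = 3000, 36
        est = {}
        for lam in (1.0, 2.0):
            ys = rng.poisson(lam, (reps, n))
            vals = np.array([constant_background_fit(row).background for row in ys])
            est[lam] = (vals.mean(), vals.std(ddof=1) / math.sqrt(reps))
        diff = est[2.0][0] - est[1.0][0]
        se = math.hypot(est[1.0][1], est[2.0][1])
        assert diff > 3 * se


class TestPlanarModel:
    def test_model_spec_coefficient_counts(self):
        assert ModelSpec("constant").n_coefficients == 1
        assert ModelSpec("planar").n_coefficients == 3
        with pytest.raises(ValueError):
            ModelSpec("quadratic")

    def test_matches_statsmodels_classical_fit(self, rng):
        """With c = inf the planar fit equals the classical Poisson GLM
        (statsmodels as the independent reference), coefficients and
        covariance alike."""
        sm = pytest.importorskip("statsmodels.api")
        n = 60
        coords = np.column_stack([rng.integers(-4, 5, n), rng.integers(-4, 5, n)])
        mu = np.exp(1.0 + 0.05 * coords[:, 0] - 0.08 * coords[:, 1])
        y = rng.poisson(mu)
        model = ModelSpec("planar")
        fit = robust_glm_fit(y, model, coords, RobustFitConfig(c=math.inf))
        X = design_matrix(model, coords.astype(float), n)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.covariance, ref.cov_params(), atol=1e-6)

    def test_planar_recovery_small_gradients(self):
        """Log-plane backgrounds with small gradients are recovered with
        coefficient bias below 3 MC standard errors."""
        from robustbg.simulate import ShoeboxSpec, simulate_shoebox

        true_beta = np.array([math.log(2.0), 0.03, -0.02])
        est = []
        for i in range(500):
            sb = simulate_shoebox(
                ShoeboxSpec(background=tuple(true_beta)),
                rng=np.random.default_rng(np.random.SeedSequence(77, spawn_key=(i,))),
            )
            fit = robust_glm_fit(
                sb.background_values,
                ModelSpec("planar", origin=sb.peak),
                sb.background_coords(),
            )
            if fit.converged:
                est.append(fit.beta)
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / math.sqrt(est.shape[0])
        assert np.all(np.abs(est.mean(axis=0) - true_beta) < 3 * se)

    def test_planar_origin_must_be_supplied_with_coords(self):
        with pytest.raises(ValueError):
            robust_glm_fit([1, 2, 3, 4], ModelSpec("planar"), coords=None)


class TestFastPath:
    def test_trivial_cases(self):
        assert constant_background_fit([0, 0, 0, 0]).degenerate
        assert constant_background_fit([2, 2, 2]).background == pytest.approx(2.0, rel=0.05)
        exact = constant_background_fit([2, 2, 2], RobustFitConfig(c=math.inf))
        assert exact.background == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("lam", [0.2, 1.0, 5.0, 20.0])
    def test_agrees_with_general_path(self, lam, rng):
        for _ in range(25):
            y = rng.poisson(lam, 100)
            fast = constant_background_fit(y)
            slow = robust_glm_fit(y)
            assert fast.background == pytest.approx(slow.background, abs=1e-8)

    def test_agrees_with_outliers_present(self, rng):
        y = rng.poisson(1.0, 50)
        y[:3] = [500, 1000, 65535]
        fast = constant_background_fit(y)
        slow = robust_glm_fit(y)
        assert fast.background == pytest.approx(slow.background, abs=1e-8)


class TestCovariance:
    def test_infinite_c_fisher_information(self, rng):
        """At c = inf the covariance is the inverse Fisher information of
        the intercept-only log-link Poisson model, 1/(n mu)."""
        y = rng.poisson(5.0, 20)
        fit = constant_background_fit(y, RobustFitConfig(c=math.inf))
        assert fit.covariance[0, 0] == pytest.approx(1.0 / (20 * fit.background), rel=1e-8)

    def test_predicts_empirical_variance(self):
        """Sandwich variance matches the spread of beta over 10^4
        replicate fits to within 10%."""
        rng = np.random.default_rng(99)
        ys = rng.poisson(5.0, (10_000, 10))
        betas, predicted = [], []
        for row in ys:
            fit = constant_background_fit(row)
            if fit.converged and fit.covariance is not None:
                betas.append(fit.beta[0])
                predicted.append(fit.covariance[0, 0])
        betas = np.asarray(betas)
        ratio = np.mean(predicted) / betas.var(ddof=1)
        assert 0.9 < ratio < 1.1

    def test_symmetric_design_decouples_intercept_and_slopes(self):
        """For a flat fit on coordinates symmetric about the origin the
        intercept-slope covariances vanish."""
        coords = np.array([(x, y) for x in range(-2, 3) for y in range(-2, 3)], float)
        n = len(coords)
        mu = np.full(n, 5.0)
        fit = glm.FitResult(
            beta=np.array([math.log(5.0), 0.0, 0.0]),
            mu=mu, covariance=None, weights=np.ones(n),
            n_iter=1, converged=True,
        )
        X = design_matrix(ModelSpec("planar"), coords, n)
        cov = estimator_covariance(fit, X, RobustFitConfig())
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert cov[0, 2] == pytest.approx(0.0, abs=1e-12)
        # symmetric positive semi-definite
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_degenerate_design_raises(self):
        coords = np.column_stack([np.arange(6.0), np.arange(6.0)])  # collinear
        n = 6
        fit = glm.FitResult(
            beta=np.array([0.0, 0.0, 0.0]), mu=np.ones(n), covariance=None,
            weights=np.ones(n), n_iter=1, converged=True,
        )
        X = design_matrix(ModelSpec("planar"), coords, n)
        with pytest.raises(np.linalg.LinAlgError):
            estimator_covariance(fit, X, RobustFitConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        RobustFitConfig(c=-1.0)
    with pytest.raises(ValueError):
        RobustFitConfig(tol=0.0)
    with pytest.raises(ValueError):
        RobustFitConfig(max_iter=0)
    with pytest.raises(ValueError):
        RobustFitConfig(c=math.inf, allow_infinite_c=False)
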