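"""Tests for the penalized scalar-on-function regression."""

import numpy as np
import pytest
from scipy import optimize

import gaitspec as gs
from gaitspec.errors import JoinError, ParameterError, RankError
from gaitspec.regression import DesignSet


def random_instance(rng, n, p, k, a=2.0, m=2):
    """A small random design with an m-column Gaussian-ish basis."""
    grid = np.linspace(0.0, 1.0, p)
    Q = np.exp(-((grid[:, None] - rng.uniform(0.2, 0.8, m)[None, :]) ** 2) / 0.02)
    Q /= np.linalg.norm(Q, axis=0)
    Lop = gs.penalty_operator(gs.projection(Q), a=a)
    ds = DesignSet(
        y=rng.normal(size=n),
        X=rng.normal(size=(n, k)),
        W=rng.normal(size=(n, p)),
        order_grid=grid,
        delta_s=grid[1] - grid[0],
        x_names=[f"x{j}" for j in range(k)],
    )
    return ds, Lop


def criterion(ds, L, lam, gamma, beta):
    resid = ds.y - ds.X @ gamma - ds.W @ beta
    return float(resid @ resid + lam * np.sum((L @ beta) ** 2))


class TestAssembleDesign:
    def test_design_shapes_for_study_cohort(self, small_cohort):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        assert ds.X.shape == (8, 4)
        assert ds.W.shape == (8, 546)
        assert ds.x_names == ["intercept", "male", "cadence", "vmc"]

    def test_spectra_carry_quadrature_weight(self, small_cohort):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        raw = small_cohort.features[0].spectrum
        assert np.allclose(ds.W[0], raw * ds.delta_s)

    def test_missing_subject_raises_with_id(self, small_cohort):
        cov = small_cohort.covariates[small_cohort.covariates["subject_id"] != "s002"]
        with pytest.raises(JoinError, match="s002"):
            gs.assemble_design(small_cohort.features, cov)

    def test_row_permutation_equivariance(self, small_cohort, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        perm = np.random.default_rng(0).permutation(len(small_cohort.features))
        feats = [small_cohort.features[i] for i in perm]
        ds2 = gs.assemble_design(feats, small_cohort.covariates)
        g1, b1 = gs.fit_generalized_ridge(ds, Lop, 1.0)
        g2, b2 = gs.fit_generalized_ridge(ds2, Lop, 1.0)
        assert np.allclose(g1, g2, atol=1e-8)
        assert np.allclose(b1, b2, atol=1e-8)


class TestGeneralizedRidge:
    def test_zero_spectra_decouple_to_ols(self):
        rng = np.random.default_rng(4)
        ds, Lop = random_instance(rng, n=20, p=6, k=3)
        ds.W = np.zeros_like(ds.W)
        gamma, beta = gs.fit_generalized_ridge(ds, Lop, lam=3.7)
        ols, *_ = np.linalg.lstsq(ds.X, ds.y, rcond=None)
        assert np.allclose(gamma, ols, atol=1e-10)
        assert np.allclose(beta, 0.0, atol=1e-10)

    def test_ridge_limit_matches_closed_form(self):
        # a = 1 and no scalar block: textbook ridge (W'W + lam I)^{-1} W'y
        rng = np.random.default_rng(8)
        n, p, lam = 15, 30, 2.5
        W = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        grid = np.linspace(0, 1, p)
        ds = DesignSet(y=y, X=np.empty((n, 0)), W=W, order_grid=grid,
                       delta_s=grid[1] - grid[0])
        Lop = gs.penalty_operator(np.zeros((p, p)), a=1.0)
        _, beta = gs.fit_generalized_ridge(ds, Lop, lam)
        closed = np.linalg.solve(W.T @ W + lam * np.eye(p), W.T @ y)
        assert np.allclose(beta, closed, atol=1e-12)

    def test_matches_generic_optimizer_on_small_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            ds, Lop = random_instance(rng, n=8, p=5, k=1)
            lam = float(rng.uniform(0.1, 5.0))
            gamma, beta = gs.fit_generalized_ridge(ds, Lop, lam)

            def obj(theta):
                return criterion(ds, Lop.L, lam, theta[:1], theta[1:])

            res = optimize.minimize(obj, np.zeros(6), method="BFGS",
                                    options={"gtol": 1e-12, "maxiter": 2000})
            ref = np.concatenate([gamma, beta])
            assert np.max(np.abs(res.x - ref)) < 1e-6

    def test_unpenalized_overparameterized_raises(self):
        rng = np.random.default_rng(2)
        ds, Lop = random_instance(rng, n=5, p=8, k=1)
        with pytest.raises(RankError):
            gs.fit_generalized_ridge(ds, Lop, lam=0.0)

    def test_negative_lambda_rejected(self):
        rng = np.random.default_rng(2)
        ds, Lop = random_instance(rng, n=8, p=4, k=1)
        with pytest.raises(ParameterError):
            gs.fit_generalized_ridge(ds, Lop, lam=-1.0)

    def test_monotone_shrinkage_in_penalty_norm(self):
        rng = np.random.default_rng(6)
        ds, Lop = random_instance(rng, n=25, p=12, k=2)
        norms = []
        for lam in (0.01, 0.1, 1.0, 10.0, 100.0):
            _, beta = gs.fit_generalized_ridge(ds, Lop, lam)
            norms.append(np.linalg.norm(Lop.L @ beta))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_large_a_targets_complement(self):
        # with fixed lambda, growing a crushes the off-span component of
        # beta while the span component persists
        rng = np.random.default_rng(13)
        grid = np.linspace(0, 1, 12)
        Q = np.exp(-((grid[:, None] - np.array([[0.3, 0.7]])) ** 2) / 0.02)
        Q /= np.linalg.norm(Q, axis=0)
        P = gs.projection(Q)
        W = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        ds = DesignSet(y=y, X=np.ones((30, 1)), W=W, order_grid=grid,
                       delta_s=grid[1] - grid[0], x_names=["intercept"])
        ratios = []
        for a in (1.0, 4.0, 16.0):
            _, beta = gs.fit_generalized_ridge(ds, gs.penalty_operator(P, a=a), lam=1.0)
            off = np.linalg.norm(beta - P @ beta)
            on = np.linalg.norm(P @ beta)
            ratios.append(off / on)
        assert ratios[0] > ratios[1] > ratios[2]


class TestREML:
    def test_lambda_is_variance_ratio(self, small_cohort, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        lam, se2, sb2 = gs.select_lambda_reml(ds, Lop)
        assert lam == pytest.approx(se2 / sb2, rel=1e-10)

    def test_pure_noise_shrinks_beta_to_noise_floor(self, Lop, ogrid):
        # without functional signal the REML variance-ratio estimate is
        # boundary-valued (lambda at the cap, sigma_beta^2 -> 0) for some
        # realizations and large-but-finite for others; in every case the
        # fitted coefficient function carries a small fraction of the
        # energy of the generator's default bump
        ref = float(np.trapezoid(gs.bump_beta(ogrid, 2.5, 50.0) ** 2, ogrid))
        capped = 0
        for seed in range(200, 204):
            spec = gs.CohortSpec(n_subjects=30, beta_true=None, sigma_eps=1.0, seed=seed)
            cohort = gs.simulate_cohort(spec)
            ds = gs.assemble_design(cohort.features, cohort.covariates)
            fit = gs.fit_functional_model(ds, Lop)
            capped += fit.lam >= 1e5
            energy = float(np.trapezoid(fit.beta_hat ** 2, ogrid))
            assert energy < 0.2 * ref
        assert capped >= 1  # boundary estimate occurs

    def test_vanishing_noise_gives_small_lambda_and_recovery(self, Lop, ogrid):
        # noiseless cohort with a real bump: REML prefers minimal shrinkage
        # and the estimate approaches the truth within span(Q)
        beta_true = gs.bump_beta(ogrid, 2.5, 50.0)
        cohort = gs.simulate_cohort(gs.CohortSpec(
            n_subjects=46, beta_true=beta_true, sigma_eps=0.0, seed=42))
        ds = gs.assemble_design(cohort.features, cohort.covariates)
        fit = gs.fit_functional_model(ds, Lop)
        assert fit.lam < 1e-4
        ise = float(np.trapezoid((fit.beta_hat - beta_true) ** 2, ogrid))
        assert ise < 0.15 * float(np.trapezoid(beta_true ** 2, ogrid))


class TestBandsAndSignificance:
    def test_bands_contain_estimate_and_shrink_with_noise(self, small_cohort, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        _, beta, _, lower, upper = gs.confidence_bands(ds, Lop, lam=1.0, sigma_eps2=1.0)
        assert np.all(lower <= beta) and np.all(beta <= upper)
        _, _, _, l0, u0 = gs.confidence_bands(ds, Lop, lam=1.0, sigma_eps2=0.0)
        assert np.allclose(u0 - l0, 0.0)

    def test_band_width_scales_with_normal_quantile(self, small_cohort, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        _, _, _, l95, u95 = gs.confidence_bands(ds, Lop, 1.0, 1.0, level=0.95)
        _, _, _, l80, u80 = gs.confidence_bands(ds, Lop, 1.0, 1.0, level=0.80)
        ratio = (u95 - l95) / (u80 - l80)
        assert np.allclose(ratio, 1.959964 / 1.281552, atol=1e-5)

    def test_sandwich_variant_differs_but_is_valid(self, small_cohort, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        _, beta, cov, lower, upper = gs.confidence_bands(
            ds, Lop, 1.0, 1.0, method="sandwich")
        assert np.all(lower <= beta) and np.all(beta <= upper)
        assert np.all(np.diag(cov) >= 0)

    def test_null_bands_give_empty_set(self, ogrid):
        fit = gs.FunctionalFit(
            gamma_hat=np.zeros(1), beta_hat=np.zeros(546), lam=1.0,
            sigma_eps2=1.0, sigma_beta2=1.0, cov_coef=np.eye(2),
            band_lower=np.full(546, -1.0), band_upper=np.full(546, 1.0),
            order_grid=ogrid,
        )
        assert gs.significant_multiples(fit, np.arange(0.5, 5.51, 0.5)) == []

    def test_output_subset_of_centers(self, small_cohort, basis, Lop):
        ds = gs.assemble_design(small_cohort.features, small_cohort.covariates)
        fit = gs.fit_functional_model(ds, Lop)
        sig = gs.significant_multiples(fit, basis.centers)
        assert set(sig) <= set(basis.centers.tolist())
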