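import numpy as np
import pytest

import fixelharm
from fixelharm import CombatModel, FixelDataMatrix, harmonize, make_template
from fixelharm.combat import (
    apply_adjustment,
    batch_moments,
    eb_shrink,
    estimate_hyperparameters,
    fit_glm,
    standardize,
)
from fixelharm.errors import DesignError, ValidationError
from fixelharm.simulate import SimulationConfig, simulate_travelling

from conftest import direct_combat_oracle, make_covariates, random_instance


def _matrix(Y, metric="FD"):
    return FixelDataMatrix(Y=np.asarray(Y, float),
                           scan_ids=[f"s{i}" for i in range(len(Y))],
                           metric=metric)


class TestFitGlm:
    def test_two_equal_batches_symmetric_split(self):
        """Batch means 0 and 2 give alpha=1 and gamma = (-1, +1)."""
        covars = make_covariates(["a"] * 4 + ["b"] * 4)
        Y = _matrix(np.concatenate([np.zeros(4), np.full(4, 2.0)])[:, None])
        alpha, beta, sigma, gamma_raw, n_i = fit_glm(Y, covars, covariate_columns=())
        np.testing.assert_allclose(alpha, [1.0], atol=1e-10)
        np.testing.assert_allclose(gamma_raw[:, 0], [-1.0, 1.0], atol=1e-10)
        assert list(n_i) == [4, 4]

    def test_weighted_sum_to_zero_constraint(self):
        rng = np.random.default_rng(4)
        covars = make_covariates(["a"] * 3 + ["b"] * 6, rng=rng)
        Y = _matrix(rng.normal(size=(9, 5)))
        alpha, _, _, gamma_raw, n_i = fit_glm(Y, covars)
        np.testing.assert_allclose(n_i @ gamma_raw, 0.0, atol=1e-8)

    def test_matches_per_fixel_normal_equations(self):
        """Vectorised fit equals an independent per-fixel OLS solution."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        covars = make_covariates(["a"] * 4 + ["b"] * 4, rng=rng)
        Y = _matrix(rng.normal(0.5, 0.2, size=(8, 3)))
        alpha, beta, sigma, gamma_raw, n_i = fit_glm(Y, covars,
                                                     covariate_columns=("age",))
        age = covars.df["age"].to_numpy()
        dummy_b = (covars.df["batch"] == "b").to_numpy(float)
        for f in range(3):
            D = np.column_stack([np.ones(8), dummy_b, age])
            fit = sm.OLS(Y.Y[:, f], D).fit()
            shift = fit.params[1] * n_i[1] / 8.0
            np.testing.assert_allclose(alpha[f], fit.params[0] + shift, atol=1e-8)
            np.testing.assert_allclose(gamma_raw[1, f] - gamma_raw[0, f],
                                       fit.params[1], atol=1e-8)
            np.testing.assert_allclose(beta[0, f], fit.params[2], atol=1e-8)
            np.testing.assert_allclose(sigma[f],
                                       np.sqrt(np.mean(fit.resid**2)), atol=1e-10)

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(5)
        covars = make_covariates(["a"] * 4 + ["b"] * 4, rng=rng,
                                 extra={"dummy": [0.0] * 4 + [1.0] * 4})
        Y = _matrix(rng.normal(size=(8, 2)))
        with pytest.raises(DesignError, match="batch"):
            fit_glm(Y, covars, covariate_columns=("dummy",))

    def test_constant_fixel_dropped_from_mask(self):
        rng = np.random.default_rng(6)
        Y = np.column_stack([np.full(6, 0.7), rng.normal(size=6)])
        covars = make_covariates(["a"] * 6, rng=rng)
        harmonised, model = harmonize(_matrix(Y), covars, covariate_columns=(),
                                      method="direct")
        assert not model.mask[0] and model.mask[1]
        np.testing.assert_array_equal(harmonised.Y[:, 0], Y[:, 0])


class TestStandardize:
    def test_construction_recovers_z(self):
        rng = np.random.default_rng(7)
        n, m = 12, 4
        covars = make_covariates(["a"] * 6 + ["b"] * 6, rng=rng)
        z = rng.normal(size=(n, m))
        z -= z.mean(axis=0)  # batch-free residuals
        alpha = rng.uniform(0.3, 0.7, m)
        beta = rng.normal(0, 0.01, (3, m))
        sigma = rng.uniform(0.5, 1.5, m)
        X = covars.df[["age", "sex", "icv"]].to_numpy(float)
        Y = _matrix(alpha + X @ beta + sigma * z)
        a, b, s, g, _ = fit_glm(Y, covars)
        std = standardize(Y, a, b, s, covars)
        # pooled mean exactly 0 per fixel
        np.testing.assert_allclose(std.Z.mean(axis=0), 0.0, atol=1e-6)
        # inverse transform reconstructs Y
        back = a[None, :] + X @ b + s[None, :] * std.Z
        np.testing.assert_allclose(back, Y.Y, atol=1e-8)


class TestHyperparameters:
    def test_constant_gamma_row(self):
        gamma = np.full((1, 5), 2.5)
        delta2 = np.ones((1, 5)) + np.linspace(0, 0.4, 5)
        gbar, tau2, lam, theta, fb = estimate_hyperparameters(gamma, delta2)
        assert gbar[0] == pytest.approx(2.5)
        assert tau2[0] == pytest.approx(0.0)

    def test_moment_matching_closed_form(self):
        """delta2 with mean 2 and variance 1 maps to InverseGamma(6, 10).

        Check: InverseGamma(6, 10) has mean theta/(lambda-1) = 2 and variance
        theta^2/((lambda-1)^2 (lambda-2)) = 1, so the mapping inverts the
        distribution's first two moments.
        """
        lam, theta = 6.0, 10.0
        assert theta / (lam - 1) == pytest.approx(2.0)
        assert theta**2 / ((lam - 1) ** 2 * (lam - 2)) == pytest.approx(1.0)
        # a sample with exactly m=2, V=1 (ddof=1)
        d2 = np.array([2.0 - np.sqrt(0.5), 2.0, 2.0 + np.sqrt(0.5)])
        d2 = 2.0 + (d2 - d2.mean()) / d2.std(ddof=1)
        gamma = np.zeros((1, 3))
        _, _, lam_hat, theta_hat, _ = estimate_hyperparameters(gamma, d2[None, :])
        assert lam_hat[0] == pytest.approx(6.0, abs=1e-10)
        assert theta_hat[0] == pytest.approx(10.0, abs=1e-10)

    def test_monte_carlo_recovery(self):
        from scipy import stats

        rng = np.random.default_rng(42)
        d2 = stats.invgamma.rvs(a=6, scale=10, size=10**5, random_state=rng)
        g = rng.normal(0.3, 0.1, size=10**5)
        gbar, tau2, lam, theta, _ = estimate_hyperparameters(g[None, :], d2[None, :])
        assert lam[0] == pytest.approx(6.0, rel=0.05)
        assert theta[0] == pytest.approx(10.0, rel=0.05)
        assert gbar[0] == pytest.approx(0.3, abs=3 * 0.1 / np.sqrt(10**5))


class TestEbShrink:
    def _setup(self, seed=9, m=20, n=10):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(2 * n, m))
        codes = np.repeat([0, 1], n)
        gamma_hat, delta2_hat = batch_moments(Z, codes)
        return Z, codes, gamma_hat, delta2_hat

    def test_zero_tau2_gives_complete_shrinkage(self):
        Z, codes, gh, dh = self._setup()
        gbar = gh.mean(axis=1)
        tau2 = np.zeros(2)
        lam = np.full(2, 6.0)
        theta = np.full(2, 10.0)
        gs, ds, conv = eb_shrink(Z, codes, gh, dh, gbar, tau2, lam, theta)
        for b in range(2):
            np.testing.assert_allclose(gs[b], gbar[b], atol=1e-10)

    def test_huge_tau2_gives_no_shrinkage(self):
        Z, codes, gh, dh = self._setup()
        gbar = gh.mean(axis=1)
        tau2 = np.full(2, 1e12)
        m, V = dh.mean(axis=1), dh.var(axis=1, ddof=1)
        lam = (m**2 + 2 * V) / V
        theta = (m**3 + m * V) / V
        gs, ds, conv = eb_shrink(Z, codes, gh, dh, gbar, tau2, lam, theta)
        np.testing.assert_allclose(gs, gh, atol=1e-4)

    def test_fixed_point_matches_long_run_iteration(self):
        """Converged result equals a 1000-iteration brute-force loop."""
        Z, codes, gh, dh = self._setup(seed=21, m=50, n=10)
        gbar, tau2, lam, theta, _ = estimate_hyperparameters(gh, dh)
        gs, ds, conv = eb_shrink(Z, codes, gh, dh, gbar, tau2, lam, theta,
                                 tol=1e-10, max_iter=5000)
        assert conv.all()
        for b in range(2):
            rows = Z[codes == b]
            n = rows.shape[0]
            g, d2 = gh[b].copy(), dh[b].copy()
            for _ in range(1000):  # independent scalar-formula loop
                g = (n * tau2[b] * gh[b] + d2 * gbar[b]) / (n * tau2[b] + d2)
                d2 = (theta[b] + 0.5 * ((rows - g) ** 2).sum(axis=0)) / (
                    n / 2 + lam[b] - 1)
            np.testing.assert_allclose(gs[b], g, atol=1e-8)
            np.testing.assert_allclose(ds[b] ** 2, d2, atol=1e-8)


class TestApplyAdjustment:
    def test_identity_adjustment_is_identity(self):
        rng = np.random.default_rng(10)
        covars = make_covariates(["a"] * 5 + ["b"] * 5, rng=rng)
        Y = _matrix(rng.normal(0.5, 0.1, size=(10, 4)))
        _, model = harmonize(Y, covars, method="direct")
        model.gamma_star[:] = 0.0
        model.delta_star[:] = 1.0
        out = apply_adjustment(Y, model, covars)
        np.testing.assert_allclose(out.Y, Y.Y, atol=1e-10)

    def test_single_batch_passthrough(self):
        rng = np.random.default_rng(12)
        covars = make_covariates(["solo"] * 8, rng=rng)
        Y = _matrix(rng.normal(0.5, 0.1, size=(8, 6)))
        for method in ("direct", "eb"):
            out, model = harmonize(Y, covars, method=method)
            np.testing.assert_allclose(out.Y, Y.Y, atol=1e-8)

    def test_direct_two_batch_toy_matches_oracle(self):
        rng = np.random.default_rng(13)
        Y, covars, cols = random_instance(rng, n_per_batch=(3, 3), m=3)
        out, _ = harmonize(Y, covars, covariate_columns=cols, method="direct")
        X = covars.df[list(cols)].to_numpy(float)
        expected = direct_combat_oracle(Y.Y, list(covars.df["batch"]), X)
        np.testing.assert_allclose(out.Y, expected, atol=1e-8)


class TestHarmonize:
    def test_batch_means_removed_direct_no_covariates(self):
        rng = np.random.default_rng(14)
        covars = make_covariates(["a"] * 6 + ["b"] * 9, rng=rng)
        Y = _matrix(rng.normal(0.5, 0.1, size=(15, 8))
                    + np.repeat([0.0, 0.08], [6, 9])[:, None])
        out, _ = harmonize(Y, covars, covariate_columns=(), method="direct")
        pooled = out.Y.mean(axis=0)
        for lab in ("a", "b"):
            rows = out.Y[(covars.df["batch"] == lab).to_numpy()]
            np.testing.assert_allclose(rows.mean(axis=0), pooled, atol=1e-8)

    def test_scale_equalised_across_batches(self):
        """Post-harmonisation per-batch residual SDs agree (direct exactly)."""
        template = make_template((6, 6, 3), (1, 3), seed=15)
        cfg = SimulationConfig(mode="scanner_diff", n_subjects=20, seed=15)
        ds = simulate_travelling(template, cfg)
        codes = ds.covariates.batch_codes
        for method, tol in (("direct", 0.05), ("eb", 0.15)):
            out, model = harmonize(ds.Y, ds.covariates, method=method)
            resid = out.Y - out.Y.mean(axis=0)
            sds = []
            for c in np.unique(codes):
                rows = out.Y[codes == c]
                sds.append((rows - rows.mean(axis=0)).std(axis=0, ddof=1))
            ratio = sds[0][model.mask] / sds[1][model.mask]
            assert np.median(np.abs(ratio - 1)) < tol

    def test_refit_near_idempotent(self):
        """Re-fitting on harmonised output finds near-null batch effects.

        Per-fixel batch effects drawn with realistic across-fixel spread;
        after harmonisation a refit should find no systematic batch location
        (per-batch mean of gamma-hat near 0) or scale (delta2-hat near 1);
        individual fixels retain small EB shrinkage residuals.
        """
        rng = np.random.default_rng(77)
        n_i, m = 20, 500
        labels = ["s1"] * n_i + ["s2"] * n_i + ["s3"] * n_i
        covars = make_covariates(labels, rng=rng)
        gamma = np.vstack([rng.normal(g, 1.0, size=m) for g in (0.0, 2.0, -1.0)])
        delta = np.sqrt(np.vstack([1 / rng.gamma(36.0, 1 / 35.0, size=m)
                                   for _ in range(3)]))
        codes = np.repeat([0, 1, 2], n_i)
        eps = rng.normal(size=(3 * n_i, m))
        Y = _matrix(0.5 + 0.05 * (gamma[codes] + delta[codes] * eps))
        out, _ = harmonize(Y, covars, covariate_columns=(), method="eb")
        _, refit = harmonize(out, covars, covariate_columns=(), method="eb")
        assert np.abs(refit.gamma_hat[:, refit.mask].mean(axis=1)).max() < 0.05
        assert np.abs(refit.delta2_hat[:, refit.mask].mean(axis=1) - 1).max() < 0.1

    def test_direct_equals_eb_under_flat_prior(self):
        """With tau2 huge and a flat inverse-gamma prior, EB ~ direct."""
        rng = np.random.default_rng(16)
        Y, covars, cols = random_instance(rng, n_per_batch=(6, 6), m=5)
        direct, dmodel = harmonize(Y, covars, covariate_columns=cols,
                                   method="direct")
        _, model = harmonize(Y, covars, covariate_columns=cols, method="eb")
        from fixelharm.combat import batch_moments, standardize

        std = standardize(Y, model.alpha, model.beta, model.sigma, covars, cols)
        gh, dh = batch_moments(std.Z, covars.batch_codes)
        tau2 = np.full(2, 1e12)
        lam = np.full(2, 1.0 + 1e-9)  # flat: posterior ~ likelihood
        theta = np.full(2, 1e-12)
        gs, ds, _ = eb_shrink(std.Z, covars.batch_codes, gh, dh,
                              gh.mean(axis=1), tau2, lam, theta)
        model.gamma_star, model.delta_star = gs, ds
        out = apply_adjustment(Y, model, covars)
        # flat-prior delta*^2 = sum2 / n  = delta2_hat -> matches direct
        np.testing.assert_allclose(out.Y, direct.Y, atol=1e-3)

    def test_order_equivariance(self):
        rng = np.random.default_rng(17)
        Y, covars, cols = random_instance(rng, n_per_batch=(5, 5), m=4)
        out, _ = harmonize(Y, covars, covariate_columns=cols, method="eb")
        perm = rng.permutation(Y.n_scans)
        Yp = FixelDataMatrix(Y=Y.Y[perm], scan_ids=[Y.scan_ids[i] for i in perm],
                             metric="FD")
        import fixelharm.fixel_io as fio

        covp = fio.CovariateTable(covars.df.iloc[perm].reset_index(drop=True))
        outp, _ = harmonize(Yp, covp, covariate_columns=cols, method="eb")
        np.testing.assert_allclose(outp.Y, out.Y[perm], atol=1e-10)

    def test_per_group_single_batch_group_passthrough(self):
        rng = np.random.default_rng(18)
        # AD entirely on one scanner; CN spans two
        covars = make_covariates(["x"] * 4 + ["y", "y", "z", "z"], rng=rng,
                                 extra={"group": ["AD"] * 4 + ["CN"] * 4})
        Y = _matrix(rng.normal(0.5, 0.1, size=(8, 3)))
        out, models = harmonize(Y, covars, covariate_columns=(), method="direct",
                                group_column="group")
        ad_rows = (covars.df["group"] == "AD").to_numpy()
        np.testing.assert_array_equal(out.Y[ad_rows], Y.Y[ad_rows])
        assert models["AD"] is None and models["CN"] is not None

    def test_model_round_trip_serialization(self, tmp_path):
        rng = np.random.default_rng(19)
        Y, covars, cols = random_instance(rng, n_per_batch=(5, 5), m=4)
        out, model = harmonize(Y, covars, covariate_columns=cols, method="eb")
        path = tmp_path / "model.zip"
        model.save(path)
        back = CombatModel.load(path)
        np.testing.assert_allclose(back.gamma_star, model.gamma_star)
        np.testing.assert_allclose(back.delta_star, model.delta_star)
        assert back.batch_levels == model.batch_levels
        assert back.method == model.method
        # a held-out application with the loaded model matches
        re_out = apply_adjustment(Y, back, covars)
        np.testing.assert_allclose(re_out.Y, out.Y, atol=1e-12)

    def test_output_finite_and_may_go_negative(self):
        rng = np.random.default_rng(20)
        covars = make_covariates(["a"] * 5 + ["b"] * 5, rng=rng)
        Y = _matrix(np.abs(rng.normal(0.02, 0.05, size=(10, 6))))
        out, _ = harmonize(Y, covars, covariate_columns=(), method="direct")
        assert np.all(np.isfinite(out.Y))
        clipped, _ = harmonize(Y, covars, covariate_columns=(), method="direct",
                               clip_negative=True)
        assert np.all(clipped.Y >= 0)
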