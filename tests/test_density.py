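"""Kernel marginals, Gaussian copula and the Sklar joint density."""

import numpy as np
import pytest
from scipy import integrate, stats

import tsselect as ts
from tsselect.density import marginal_log_pdf
from tsselect.errors import DataError


def _dataset(matrix, t=0.0):
    matrix = np.asarray(matrix, dtype=float)
    return ts.TSSDataset(
        matrix, t,
        [f"p{k}" for k in range(matrix.shape[1])],
        [f"c{j}" for j in range(matrix.shape[0])],
    )


class TestMarginal:
    def test_silverman_bandwidth_hand_computed(self):
        # two log-points {1, 3}: sd = sqrt(2), IQR = 1 (interpolated quartiles
        # 1.5 and 2.5), so b = 0.9 * min(sqrt(2), 1/1.34) * 2^(-1/5)
        m = ts.fit_marginal([np.e, np.e**3])
        expected = 0.9 * min(np.sqrt(2.0), 1.0 / 1.34) * 2 ** (-0.2)
        assert m.bandwidth == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(np.sort(m.log_points), [1.0, 3.0])

    def test_constant_column_rejected_with_actionable_message(self):
        with pytest.raises(DataError, match="zero spread"):
            ts.fit_marginal([2.0, 2.0, 2.0], name="Syk")

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DataError):
            ts.fit_marginal([1.0, -2.0, 3.0])

    def test_pdf_peak_of_single_effective_point(self):
        p, b = 1.7, 0.3
        m = ts.MarginalModel(log_points=np.array([p, p]), bandwidth=b)
        y = np.exp(p)
        expected = 1.0 / (b * np.sqrt(2 * np.pi) * y)
        assert ts.marginal_pdf(m, y) == pytest.approx(expected, rel=1e-12)

    def test_pdf_matches_brute_force_kernel_sum(self, rng):
        pts = rng.normal(1.0, 0.7, size=60)
        m = ts.MarginalModel(log_points=pts, bandwidth=0.25)
        ys = rng.lognormal(1.0, 1.0, size=100)
        brute = np.array([
            np.mean(stats.norm.pdf((np.log(y) - pts) / 0.25)) / (0.25 * y)
            for y in ys
        ])
        np.testing.assert_allclose(ts.marginal_pdf(m, ys), brute, rtol=1e-12)

    def test_pdf_integrates_to_one(self, rng):
        m = ts.fit_marginal(rng.lognormal(0.5, 0.6, size=200))
        val, _ = integrate.quad(
            lambda y: ts.marginal_pdf(m, y), 1e-9, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_close_to_analytic_lognormal(self, rng):
        """KDE of a lognormal(0,1) sample approaches the true pdf.

        The absolute error carries a 1/y Jacobian factor, so the sampling
        noise of the estimate grows toward the origin; the bound is looser on
        the first decade than on the bulk of the support.
        """
        sample = rng.lognormal(0.0, 1.0, size=5000)
        m = ts.fit_marginal(sample)
        grid = np.linspace(0.1, 10.0, 400)
        kde = ts.marginal_pdf(m, grid)
        truth = stats.lognorm.pdf(grid, s=1.0)
        assert np.max(np.abs(kde - truth)[grid >= 0.25]) < 0.05
        assert np.max(np.abs(kde - truth)) < 0.12

    def test_cdf_properties(self, rng):
        m = ts.fit_marginal(rng.lognormal(1.0, 0.5, size=300))
        ys = np.linspace(0.2, 30.0, 50)
        cdf = ts.marginal_cdf(m, ys)
        assert np.all(np.diff(cdf) >= 0)
        assert ts.marginal_cdf(m, 1e-12) < 1e-9
        assert ts.marginal_cdf(m, 1e12) > 1 - 1e-9

    def test_cdf_at_kernel_center_is_half(self):
        m = ts.MarginalModel(log_points=np.array([0.4, 0.4, 0.4]), bandwidth=0.2)
        assert ts.marginal_cdf(m, np.exp(0.4)) == pytest.approx(0.5, abs=1e-14)

    def test_cdf_matches_integrated_pdf(self, rng):
        m = ts.fit_marginal(rng.lognormal(0.0, 0.4, size=100))
        for y in [0.4, 1.0, 2.5]:
            quad, _ = integrate.quad(
                lambda v: ts.marginal_pdf(m, v), 1e-12, y, limit=200
            )
            assert ts.marginal_cdf(m, y) == pytest.approx(quad, abs=1e-6)

    def test_log_pdf_finite_far_in_tails(self, rng):
        m = ts.fit_marginal(rng.lognormal(0.0, 0.3, size=50))
        assert np.isfinite(marginal_log_pdf(m, 1e-15))
        assert np.isfinite(marginal_log_pdf(m, 1e15))


class TestCopula:
    def test_independent_columns_near_identity(self, rng):
        X = rng.lognormal(1.0, 0.5, size=(5000, 3))
        R = ts.fit_copula(_dataset(X)).correlation
        off = R[np.triu_indices(3, k=1)]
        assert np.max(np.abs(off)) < 4.0 / np.sqrt(5000)

    def test_comonotone_transform_gives_unit_correlation(self, rng):
        x = rng.normal(0.0, 1.0, size=5000)
        X = np.column_stack([np.exp(x), np.exp(np.exp(x) / 10.0)])
        R = ts.fit_copula(_dataset(X)).correlation
        assert R[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_result_is_valid_correlation(self, rng):
        X = rng.lognormal(0.0, 1.0, size=(200, 4))
        R = ts.fit_copula(_dataset(X)).correlation
        np.testing.assert_allclose(R, R.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-14)
        assert np.linalg.eigvalsh(R).min() > 1e-10

    def test_heavy_ties_rejected(self):
        col = np.ones(100)
        col[:10] = np.arange(1, 11)
        X = np.column_stack([col, np.linspace(1, 2, 100)])
        with pytest.raises(DataError, match="ties"):
            ts.fit_copula(_dataset(X))

    def test_identity_copula_density_is_one(self, rng):
        cop = ts.CopulaModel(np.eye(4))
        u = rng.uniform(0.05, 0.95, size=(20, 4))
        np.testing.assert_allclose(ts.copula_density(cop, u), 1.0, rtol=1e-12)

    def test_median_point_density_is_inverse_sqrt_det(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        cop = ts.CopulaModel(R)
        expected = 1.0 / np.sqrt(np.linalg.det(R))
        assert ts.copula_density(cop, [0.5, 0.5]) == pytest.approx(expected, rel=1e-12)

    def test_bivariate_density_direct_matrix_evaluation(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        cop = ts.CopulaModel(R)
        u = np.array([0.5, stats.norm.cdf(1.0)])
        z = stats.norm.ppf(u)
        expected = (
            np.linalg.det(R) ** -0.5
            * np.exp(-0.5 * z @ (np.linalg.inv(R) - np.eye(2)) @ z)
        )
        assert ts.copula_density(cop, u) == pytest.approx(expected, rel=1e-10)

    def test_boundary_arguments_rejected(self):
        cop = ts.CopulaModel(np.eye(2))
        with pytest.raises(DataError):
            ts.copula_density(cop, [0.0, 0.5])


class TestJointDensity:
    def test_independence_copula_reduces_to_marginal_product(self, rng):
        X = rng.lognormal(1.0, 0.4, size=(200, 3))
        model = ts.fit_joint_density(_dataset(X))
        forced = ts.JointDensityModel(
            marginals=model.marginals, copula=ts.CopulaModel(np.eye(3)),
            cdf_clip=model.cdf_clip,
        )
        ys = rng.lognormal(1.0, 0.4, size=(50, 3))
        expected = sum(
            marginal_log_pdf(m, ys[:, k]) for k, m in enumerate(model.marginals)
        )
        np.testing.assert_allclose(
            ts.joint_log_density(forced, ys), expected, rtol=0, atol=1e-12
        )

    def test_matches_independent_composition(self, rng):
        X = rng.lognormal(0.5, 0.5, size=(300, 3))
        model = ts.fit_joint_density(_dataset(X))
        y = rng.lognormal(0.5, 0.5, size=3)
        u = np.array([
            np.clip(ts.marginal_cdf(m, y[k]), model.cdf_clip, 1 - model.cdf_clip)
            for k, m in enumerate(model.marginals)
        ])
        by_hand = ts.copula_log_density(model.copula, u) + sum(
            marginal_log_pdf(m, y[k]) for k, m in enumerate(model.marginals)
        )
        assert ts.joint_log_density(model, y) == pytest.approx(by_hand, abs=1e-12)

    def test_finite_everywhere(self, rng):
        X = rng.lognormal(2.0, 0.3, size=(100, 2))
        model = ts.fit_joint_density(_dataset(X))
        extremes = np.array([[1e-12, 1e12], [1e12, 1e-12], [1e-12, 1e-12]])
        vals = ts.joint_log_density(model, extremes)
        assert np.all(np.isfinite(vals))

    def test_fitting_is_deterministic(self, rng):
        X = rng.lognormal(1.0, 0.5, size=(100, 2))
        m1 = ts.fit_joint_density(_dataset(X))
        m2 = ts.fit_joint_density(_dataset(X))
        np.testing.assert_array_equal(m1.copula.correlation, m2.copula.correlation)
        y = np.array([3.0, 2.0])
        assert ts.joint_log_density(m1, y) == ts.joint_log_density(m2, y)

    def test_independence_factorization_statistical(self, rng):
        """For independent columns the joint log-density is close to the sum
        of marginal log-pdfs (copula correction ~ 0) at typical points."""
        X = rng.lognormal(1.0, 0.4, size=(5000, 2))
        model = ts.fit_joint_density(_dataset(X))
        ys = rng.lognormal(1.0, 0.4, size=(300, 2))
        joint = ts.joint_log_density(model, ys)
        marg = sum(marginal_log_pdf(m, ys[:, k]) for k, m in enumerate(model.marginals))
        assert np.median(np.abs(joint - marg)) < 0.02

    def test_bivariate_lognormal_mode_density(self, rng):
        """Fitted on correlated lognormal data, the joint density matches the
        analytic bivariate lognormal density near the distribution's mode."""
        mu = np.array([1.0, 2.0])
        sd = np.array([0.5, 0.4])
        rho = 0.6
        cov = np.array([
            [sd[0] ** 2, rho * sd[0] * sd[1]],
            [rho * sd[0] * sd[1], sd[1] ** 2],
        ])
        Z = rng.multivariate_normal(mu, cov, size=5000)
        model = ts.fit_joint_density(_dataset(np.exp(Z)))
        y_mode = np.exp(mu - sd**2)  # mode of the bivariate lognormal
        log_true = (
            stats.multivariate_normal(mu, cov).logpdf(np.log(y_mode))
            - np.sum(np.log(y_mode))
        )
        fitted = ts.joint_log_density(model, y_mode)
        assert np.exp(fitted) == pytest.approx(np.exp(log_true), rel=0.10)

    def test_permutation_equivariance(self, rng):
        X = np.exp(rng.multivariate_normal(
            [1.0, 2.0, 0.5],
            [[0.3, 0.1, 0.05], [0.1, 0.2, 0.08], [0.05, 0.08, 0.25]],
            size=400,
        ))
        perm = [2, 0, 1]
        m = ts.fit_joint_density(_dataset(X))
        mp = ts.fit_joint_density(_dataset(X[:, perm]))
        y = rng.lognormal(1.0, 0.4, size=3)
        assert ts.joint_log_density(m, y) == pytest.approx(
            ts.joint_log_density(mp, y[perm]), abs=1e-12
        )
        np.testing.assert_allclose(
            mp.copula.correlation,
            m.copula.correlation[np.ix_(perm, perm)],
            atol=1e-14,
        )

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.lognormal(1.0, 0.5, size=(150, 3))
        model = ts.fit_joint_density(_dataset(X))
        p = tmp_path / "density.json"
        ts.save_joint_density(model, p)
        back = ts.load_joint_density(p)
        assert back.protein_names == model.protein_names
        y = rng.lognormal(1.0, 0.5, size=(20, 3))
        np.testing.assert_array_equal(
            ts.joint_log_density(back, y), ts.joint_log_density(model, y)
        )

    def test_load_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(DataError):
            ts.load_joint_density(p)

    def test_gaussian_closure_in_logs(self, rng):
        """Kernel marginals + Gaussian copula fitted to a multivariate
        lognormal reproduce its log-density to small median error."""
        d = 3
        mu = np.array([5.0, 7.0, 5.5])
        sd = np.sqrt([0.15, 0.06, 0.15])
        corr = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        cov = corr * np.outer(sd, sd)
        Z = rng.multivariate_normal(mu, cov, size=10_000)
        model = ts.fit_joint_density(_dataset(np.exp(Z)))
        Zh = rng.multivariate_normal(mu, cov, size=1000)
        Yh = np.exp(Zh)
        truth = stats.multivariate_normal(mu, cov).logpdf(Zh) - Zh.sum(axis=1)
        fitted = ts.joint_log_density(model, Yh)
        assert np.median(np.abs(fitted - truth)) < 0.05
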