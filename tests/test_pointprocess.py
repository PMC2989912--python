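"""Kernel surfaces, Poisson process fits, bandwidth selection, simulation,
envelopes."""

import numpy as np
import pytest
from scipy import optimize

from fruitscape import (PointPattern, fit_homogeneous_poisson,
                        fit_inhomogeneous_poisson, gof_envelope,
                        kernel_density_surface, optimize_sigma, rectangle_window,
                        simulate_poisson)
from fruitscape.pointprocess import DensitySurface, kernel_density_at


def _standardize(surf):
    v = surf.values
    surf.values = (v - v[surf.mask].mean()) / v[surf.mask].std()
    return surf


class TestKernelSurface:
    def test_gaussian_peak_closed_form(self, plot_window):
        """A single unit-weight point far from edges peaks at 1/(2 pi s^2)."""
        pat = PointPattern(np.array([500.0]), np.array([250.0]), plot_window)
        val = kernel_density_at(pat.x, pat.y, 500.0, 250.0, 172.0)[0]
        assert val == pytest.approx(1.0 / (2 * np.pi * 172.0**2), abs=1e-9)

    def test_integral_recovers_total_weight(self, rng):
        win = rectangle_window(4000.0, 4000.0)
        pat = PointPattern(rng.uniform(500, 3500, 30), rng.uniform(500, 3500, 30), win)
        surf = kernel_density_surface(pat, sigma=100.0, cell=20.0, edge_correct=True)
        assert surf.integral() == pytest.approx(30.0, rel=1e-3)

    def test_linearity_in_points(self, plot_window):
        a = PointPattern(np.array([300.0]), np.array([200.0]), plot_window)
        b = PointPattern(np.array([700.0]), np.array([300.0]), plot_window)
        ab = PointPattern(np.array([300.0, 700.0]), np.array([200.0, 300.0]), plot_window)
        kw = dict(sigma=120.0, cell=50.0, edge_correct=False)
        sa = kernel_density_surface(a, **kw)
        sb = kernel_density_surface(b, **kw)
        sab = kernel_density_surface(ab, **kw)
        assert np.allclose(sab.values, sa.values + sb.values)

    def test_translation_invariance(self, rng):
        win1 = rectangle_window(1000, 500)
        x, y = rng.uniform(100, 900, 20), rng.uniform(100, 400, 20)
        s1 = kernel_density_surface(PointPattern(x, y, win1), 80.0, cell=25.0)
        win2 = rectangle_window(1000, 500, x0=5000.0, y0=-300.0)
        s2 = kernel_density_surface(PointPattern(x + 5000.0, y - 300.0, win2), 80.0,
                                    cell=25.0)
        assert np.allclose(s1.values, s2.values)

    def test_empty_pattern_warns_zero_surface(self, plot_window):
        pat = PointPattern(np.empty(0), np.empty(0), plot_window)
        with pytest.warns(UserWarning):
            surf = kernel_density_surface(pat, 100.0, cell=50.0)
        assert np.all(surf.values == 0.0)

    def test_ascii_grid_roundtrip(self, tmp_path, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 15), rng.uniform(0, 500, 15), plot_window)
        surf = kernel_density_surface(pat, 100.0, cell=50.0)
        surf.to_ascii_grid(tmp_path / "s.asc")
        back = DensitySurface.from_ascii_grid(tmp_path / "s.asc")
        assert back.cell == surf.cell
        assert np.allclose(back.values[back.mask], surf.values[surf.mask], rtol=1e-9)


class TestHomogeneousFit:
    def test_mle_is_count_over_area(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 100), rng.uniform(0, 500, 100), plot_window)
        fit = fit_homogeneous_poisson(pat)
        assert fit.lambda_hat == 100 / 500_000.0  # exact, not approx

    def test_doubling_window_halves_intensity(self, rng):
        x, y = rng.uniform(0, 1000, 60), rng.uniform(0, 500, 60)
        lam1 = fit_homogeneous_poisson(PointPattern(x, y, rectangle_window(1000, 500))).lambda_hat
        lam2 = fit_homogeneous_poisson(PointPattern(x, y, rectangle_window(2000, 500))).lambda_hat
        assert lam1 == pytest.approx(2 * lam2)

    def test_matches_numeric_likelihood_maximization(self, rng, plot_window):
        """Brute-force 1-D maximization of n log(lam) - lam |A| agrees with
        the closed-form MLE."""
        pat = PointPattern(rng.uniform(0, 1000, 73), rng.uniform(0, 500, 73), plot_window)
        area = plot_window.area
        res = optimize.minimize_scalar(
            lambda lam: -(pat.n * np.log(lam) - lam * area),
            bounds=(1e-8, 1e-2), method="bounded",
            options={"xatol": 1e-16},
        )
        fit = fit_homogeneous_poisson(pat)
        assert fit.lambda_hat == pytest.approx(res.x, rel=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, rel=1e-10)

    def test_empty_pattern_zero_intensity(self, plot_window):
        pat = PointPattern(np.empty(0), np.empty(0), plot_window)
        with pytest.warns(UserWarning):
            fit = fit_homogeneous_poisson(pat)
        assert fit.lambda_hat == 0.0


@pytest.fixture(scope="module")
def covariate():
    rng = np.random.default_rng(3)
    win = rectangle_window(2000.0, 1000.0)
    seeds = PointPattern(rng.uniform(0, 2000, 40), rng.uniform(0, 1000, 40), win)
    return _standardize(kernel_density_surface(seeds, 250.0, cell=25.0,
                                               edge_correct=False))


class TestInhomogeneousFit:

    def test_constant_covariate_reduces_to_homogeneous(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 80), rng.uniform(0, 500, 80), plot_window)
        flat = kernel_density_surface(pat, 100.0, cell=50.0)
        flat.values = np.ones_like(flat.values)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_inhomogeneous_poisson(pat, flat)
        assert fit.kind == "homogeneous"
        assert fit.lambda_hat == pytest.approx(80 / 500_000.0, rel=1e-8)

    def test_parameter_recovery_within_3se(self, covariate, rng):
        alpha, beta = -7.0, 1.0
        lam = DensitySurface(covariate.x0, covariate.y0, covariate.cell,
                             np.exp(alpha + beta * covariate.values),
                             covariate.mask, covariate.window)
        win = rectangle_window(2000.0, 1000.0)
        pat = simulate_poisson(lam, win, rng)
        assert pat.n > 800
        fit = fit_inhomogeneous_poisson(pat, covariate)
        assert abs(fit.alpha - alpha) < 3 * fit.alpha_se
        assert abs(fit.beta - beta) < 3 * fit.beta_se

    def test_score_identity_expected_equals_observed(self, covariate, rng):
        lam = DensitySurface(covariate.x0, covariate.y0, covariate.cell,
                             np.exp(-7.0 + covariate.values), covariate.mask,
                             covariate.window)
        win = rectangle_window(2000.0, 1000.0)
        pat = simulate_poisson(lam, win, rng)
        fit = fit_inhomogeneous_poisson(pat, covariate)
        assert fit.expected_count() == pytest.approx(pat.n, rel=1e-6)


class TestSimulatePoisson:
    def test_zero_intensity_empty(self, plot_window, rng):
        assert simulate_poisson(0.0, plot_window, rng).n == 0

    def test_constant_intensity_poisson_moments(self, plot_window, rng):
        lam = 2e-4
        counts = np.array([simulate_poisson(lam, plot_window, rng).n for _ in range(400)])
        mean_expected = lam * plot_window.area  # 100
        assert abs(counts.mean() - mean_expected) < 3 * np.sqrt(mean_expected / 400)

    def test_two_level_step_intensity_ratio(self, rng):
        win = rectangle_window(1000.0, 500.0)
        ny, nx = 10, 20
        vals = np.full((ny, nx), 1e-4)
        vals[:, nx // 2:] = 3e-4       # right half three times denser
        surf = DensitySurface(0.0, 0.0, 50.0, vals, np.ones((ny, nx), bool), win)
        left = right = 0
        for _ in range(200):
            p = simulate_poisson(surf, win, rng)
            left += np.sum(p.x < 500.0)
            right += np.sum(p.x >= 500.0)
        assert right / left == pytest.approx(3.0, rel=0.15)


class TestOptimizeSigma:
    def test_single_element_grid(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 60), rng.uniform(0, 500, 60), plot_window)
        det = PointPattern(pat.x[::3], pat.y[::3], plot_window)
        sigma, profile = optimize_sigma(pat, det, [150.0], cell=50.0)
        assert sigma == 150.0
        assert len(profile) == 1

    def test_profile_covers_whole_grid(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 60), rng.uniform(0, 500, 60), plot_window)
        det = PointPattern(pat.x[::2], pat.y[::2], plot_window)
        grid = [80.0, 160.0, 320.0]
        _, profile = optimize_sigma(pat, det, grid, cell=50.0)
        assert [s for s, _ in profile] == grid
        assert all(np.isfinite(c) for _, c in profile)

    def test_recovers_generating_bandwidth(self):
        """Patterns whose intensity is driven by the detected-tree density
        smoothed at 150 m select a bandwidth near 150 from the grid."""
        hits = 0
        reps = 8
        win = rectangle_window(1500.0, 800.0)
        for k in range(reps):
            rng = np.random.default_rng(100 + k)
            det = simulate_poisson(1.2e-4, win, rng)
            z150 = _standardize(kernel_density_surface(det, 150.0, cell=50.0,
                                                       edge_correct=False, window=win))
            lam = DensitySurface(z150.x0, z150.y0, z150.cell,
                                 np.exp(-7.6 + 1.2 * z150.values), z150.mask, win)
            pat = simulate_poisson(lam, win, rng)
            sigma, _ = optimize_sigma(pat, det, [50.0, 100.0, 150.0, 250.0, 400.0],
                                      cell=50.0)
            hits += sigma in (100.0, 150.0, 250.0)
        assert hits >= 6


class TestEnvelope:
    def test_band_ordering_and_shape(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 150), rng.uniform(0, 500, 150),
                           plot_window)
        fit = fit_homogeneous_poisson(pat)
        env = gof_envelope(fit, pat, n_sim=39, rng=rng)
        assert np.all(env.lower <= env.mean_sim + 1e-12)
        assert np.all(env.mean_sim <= env.upper + 1e-12)
        assert env.observed.size == env.lower.size == env.upper.size

    def test_clustered_pattern_rejected_by_homogeneous_fit(self, rng, plot_window):
        """Strong clustering escapes the homogeneous model's envelope."""
        cx = rng.uniform(100, 900, 6)
        cy = rng.uniform(100, 400, 6)
        xs = np.concatenate([np.clip(c + rng.normal(0, 20, 60), 0, 1000) for c in cx])
        ys = np.concatenate([np.clip(c + rng.normal(0, 20, 60), 0, 500) for c in cy])
        pat = PointPattern(xs, ys, plot_window)
        fit = fit_homogeneous_poisson(pat)
        env = gof_envelope(fit, pat, n_sim=39, rng=rng)
        assert not env.inside

    def test_requires_enough_simulations(self, rng, plot_window):
        pat = PointPattern(rng.uniform(0, 1000, 50), rng.uniform(0, 500, 50), plot_window)
        with pytest.raises(ValueError):
            gof_envelope(fit_homogeneous_poisson(pat), pat, n_sim=5, rng=rng)
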