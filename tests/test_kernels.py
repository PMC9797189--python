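"""Release conditioning, scenario models, KDE kernels, mixtures and JSD."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from pappus import kernels as kn


class _StubFit:
    """Minimal detachment-curve stand-in with an arbitrary CDF."""

    converged = True

    def __init__(self, fn):
        self._fn = fn

    def cdf(self, u):
        return self._fn(np.asarray(u, dtype=float))


class TestReleaseSampling:
    def test_plain_bootstrap_without_fit(self):
        speeds = np.linspace(0.5, 10.0, 500)
        rng_draws = kn.sample_release_wind(speeds, None, 2000, 3)
        assert rng_draws.size == 2000
        assert set(np.round(rng_draws, 6)) <= set(np.round(speeds, 6))

    def test_uniform_acceptance_matches_bootstrap(self):
        speeds = np.linspace(0.5, 10.0, 500)
        ones = _StubFit(lambda u: np.ones_like(u))
        a = kn.sample_release_wind(speeds, ones, 5000, 3)
        b = kn.sample_release_wind(speeds, None, 5000, 3)
        ks = stats.ks_2samp(a, b)
        assert ks.pvalue > 0.01

    def test_step_threshold_excludes_low_winds(self):
        speeds = np.linspace(0.5, 10.0, 500)
        step = _StubFit(lambda u: (u > 5.0).astype(float))
        out = kn.sample_release_wind(speeds, step, 1000, 4)
        assert np.all(out > 5.0)

    def test_monotone_weighting_raises_mean(self, wind_split, detach_fits):
        pop = wind_split["wet"]
        n = 100_000
        cond = kn.sample_release_wind(pop, detach_fits["wet"], n, 5)
        boot = kn.sample_release_wind(pop, None, n, 5)
        se = pop.std() / math.sqrt(n)
        assert cond.mean() > boot.mean() + 3 * se

    def test_zero_acceptance_rejected(self):
        zero = _StubFit(lambda u: np.zeros_like(u))
        with pytest.raises(ValueError):
            kn.sample_release_wind(np.array([1.0, 2.0]), zero, 10, 1)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            kn.sample_release_wind(np.array([]), None, 10, 1)


class TestModelsAndSummaries:
    def test_summary_of_constant_sample(self):
        assert kn.summarize(np.full(100, 7.0)) == (7.0, 0.0)
        assert kn.summarize(np.full(100, 200.0)) == (200.0, 1.0)

    def test_model_specs_cover_paper_grid(self):
        assert kn.MODELS[1] == kn.ModelSpec("dry", "open", "open")
        assert kn.MODELS[3].settling_velocity == 0.7
        assert kn.MODELS[5].detach_condition == "wet"
        assert kn.ModelSpec("dry", "none", "open").detach_condition is None

    def test_run_model_reproducible_and_positive(self, wind_split, detach_fits):
        a = kn.run_model(kn.MODELS[1], wind_split, detach_fits, n=500, seed=8)
        b = kn.run_model(kn.MODELS[1], wind_split, detach_fits, n=500, seed=8)
        np.testing.assert_array_equal(a.distances, b.distances)
        assert np.all(a.distances > 0)

    def test_dry_weather_outdisperses_wet(self, wind_split, detach_fits):
        m1 = kn.run_model(kn.MODELS[1], wind_split, detach_fits, n=3000, seed=9)
        m2 = kn.run_model(kn.MODELS[2], wind_split, detach_fits, n=3000, seed=9)
        assert np.median(m1.distances) > np.median(m2.distances)


class TestKDE:
    def test_normalisation(self, wind_split, detach_fits):
        res = kn.run_model(kn.MODELS[1], wind_split, detach_fits, n=2000, seed=10)
        kernel = kn.kde(res.distances)
        assert kernel.integral() == pytest.approx(1.0, abs=1e-6)

    def test_point_mass_peaks_at_the_mass(self):
        rng = np.random.default_rng(1)
        d = 1.0 + rng.normal(0, 1e-3, 500)
        kernel = kn.kde(d)
        assert kernel.grid[np.argmax(kernel.density)] == pytest.approx(1.0, rel=0.05)

    def test_matches_lognormal_truth(self):
        rng = np.random.default_rng(2)
        mu, s = 1.0, 0.6
        d = rng.lognormal(mu, s, 10_000)
        kernel = kn.kde(d, grid_size=400)
        truth = stats.lognorm.pdf(kernel.grid, s, scale=np.exp(mu))
        mae = np.mean(np.abs(kernel.density - truth))
        assert mae < 0.10 * truth.max()
        assert kn.kernel_median(kernel) == pytest.approx(np.exp(mu), rel=0.1)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            kn.kde(np.array([1.0, -2.0] * 10))
        with pytest.raises(ValueError):
            kn.kde(np.array([1.0, 2.0]))

    def test_tail_fraction_of_known_density(self):
        rng = np.random.default_rng(3)
        d = rng.lognormal(3.0, 1.5, 20_000)
        kernel = kn.kde(d, grid_size=600)
        emp = float(np.mean(d > 100.0))
        assert kn.kernel_tail_fraction(kernel, 100.0) == pytest.approx(emp, abs=0.03)


class TestTimecourse:
    def test_never_detaches(self, wind_split):
        frac, mean_u = kn.detachment_timecourse(
            wind_split["dry"], _StubFit(lambda u: np.zeros_like(u)), duration=5000, seed=1
        )
        assert frac == 0.0
        assert math.isnan(mean_u)

    def test_always_detaches(self, wind_split):
        pop = wind_split["dry"]
        frac, mean_u = kn.detachment_timecourse(
            pop, _StubFit(lambda u: np.ones_like(u)), duration=50_000, seed=2
        )
        assert frac == 1.0
        assert abs(mean_u - pop.mean()) < 3 * pop.std() / math.sqrt(50_000)

    def test_detachment_is_wind_biased(self, wind_split, detach_fits):
        # monotone F: winds on detaching seconds exceed the unconditional mean
        pop = wind_split["dry"]
        frac, mean_u = kn.detachment_timecourse(pop, detach_fits["dry"], duration=100_000, seed=3)
        assert 0 < frac < 1
        assert mean_u > pop.mean() + 3 * pop.std() / math.sqrt(frac * 100_000)


class TestMixture:
    def test_printed_ratio_arithmetic(self):
        # dry weather 3x more frequent; detachment 8x rarer wet (morphing)
        assert kn.mixture_weights(0.75, 8.0) == pytest.approx((0.96, 0.04), abs=1e-12)
        # non-morphing: detachment only 2.5x rarer when staying open
        w_dry, w_wet = kn.mixture_weights(0.75, 2.5)
        assert (w_dry, w_wet) == pytest.approx((0.75 * 2.5 / 2.125, 0.25 / 2.125), rel=1e-12)
        assert (round(w_dry, 3), round(w_wet, 3)) == (0.882, 0.118)

    def test_combining_equal_kernels_is_identity(self):
        rng = np.random.default_rng(4)
        k = kn.kde(rng.lognormal(1, 0.5, 1000))
        combined = kn.combine_kernels(k, k, 0.7, 0.3, 0.1)
        np.testing.assert_allclose(combined.density, k.density, rtol=1e-9)

    def test_weights_normalised_and_mixture_integrates(self):
        rng = np.random.default_rng(5)
        grid = np.logspace(-2, 4, 400)
        k1 = kn.kde(rng.lognormal(1.5, 0.8, 2000), grid=grid)
        k2 = kn.kde(rng.lognormal(0.2, 0.6, 2000), grid=grid)
        comb = kn.combine_kernels(k1, k2, 0.75, 0.12, 0.015)
        assert comb.summary["w_dry"] + comb.summary["w_wet"] == pytest.approx(1.0)
        assert comb.integral() == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_weights_rejected(self):
        rng = np.random.default_rng(6)
        k = kn.kde(rng.lognormal(1, 0.5, 500))
        with pytest.raises(ValueError):
            kn.combine_kernels(k, k, 0.5, 0.0, 0.0)


def _gauss_kernel(mu, grid):
    dens = stats.norm.pdf(np.log10(grid), np.log10(np.exp(mu)), 0.2) / (grid * np.log(10))
    dens /= np.trapezoid(dens, grid)
    return kn.DispersalKernel(grid=grid, density=dens, n_events=0)


class TestJensenShannon:
    def test_self_divergence_zero(self):
        grid = np.logspace(-1, 2, 300)
        k = _gauss_kernel(1.0, grid)
        assert kn.jensen_shannon(k, k) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_maximal(self):
        grid = np.logspace(-1, 2, 400)
        lo = np.where(grid < 1.0, 1.0, 0.0)
        hi = np.where(grid > 10.0, 1.0, 0.0)
        ka = kn.DispersalKernel(grid=grid, density=lo / np.trapezoid(lo, grid), n_events=0)
        kb = kn.DispersalKernel(grid=grid, density=hi / np.trapezoid(hi, grid), n_events=0)
        assert kn.jensen_shannon(ka, kb) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_and_range(self):
        grid = np.logspace(-1, 2, 300)
        ka, kb = _gauss_kernel(0.5, grid), _gauss_kernel(1.5, grid)
        j1, j2 = kn.jensen_shannon(ka, kb), kn.jensen_shannon(kb, ka)
        assert j1 == pytest.approx(j2, rel=1e-12)
        assert 0.0 < j1 < 1.0

    def test_two_gaussians_match_quadrature_oracle(self):
        # JSD of N(0,1) vs N(1,1) by direct numerical integration (base 2)
        p = lambda x: stats.norm.pdf(x, 0, 1)
        q = lambda x: stats.norm.pdf(x, 1, 1)

        def integrand(x, f, g):
            m = 0.5 * (p(x) + q(x))
            fx = f(x)
            return fx * np.log2(fx / m) if fx > 0 else 0.0

        oracle = 0.5 * (
            quad(integrand, -12, 13, args=(p, q), limit=300)[0]
            + quad(integrand, -12, 13, args=(q, p), limit=300)[0]
        )
        # same two densities expressed as dispersal kernels in d = e^x:
        # f_d(d) = f_x(ln d) / d
        grid = np.logspace(-6, 7, 4000)
        ka = kn.DispersalKernel(grid=grid, density=stats.norm.pdf(np.log(grid), 0, 1) / grid, n_events=0)
        kb = kn.DispersalKernel(grid=grid, density=stats.norm.pdf(np.log(grid), 1, 1) / grid, n_events=0)
        assert kn.jensen_shannon(ka, kb) == pytest.approx(oracle, abs=1e-4)


def test_sensitivity_report_covers_all_constants(wind_split, detach_fits):
    table = kn.sensitivity_report(wind_split, detach_fits, n=400, seed=1)
    assert set(table["constant"]) == {"baseline", "sigma_u_coeff", "sigma_w_coeff", "tl_coeff"}
    assert len(table) == 7  # baseline + 2 factors x 3 constants
    assert np.isfinite(table["median_m"]).all()
    assert ((table["ldd_fraction"] >= 0) & (table["ldd_fraction"] <= 1)).all()
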