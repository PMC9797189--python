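"""Kaplan-Meier, log-rank and parametric detachment fits."""

import math

import numpy as np
import pytest

from pappus import survival as sv
from pappus.survival import DetachmentAssay, _gengamma_cdf, gengamma_rvs

STEPS = (2.0, 4.0, 6.0, 8.0, 9.8)


def _assay(counts, remaining, cond="dry", steps=STEPS, cid="c0"):
    return DetachmentAssay(
        capitulum_id=cid, condition=cond, steps=steps, detached_counts=counts, remaining=remaining
    )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # 10 diaspores: 5 detach at 2, 3 at 4, 2 censored
        km = sv.kaplan_meier([_assay((5, 3, 0, 0, 0), 2)])
        assert km.survival[1] == pytest.approx(0.5)  # 5/10
        assert km.survival[2] == pytest.approx(0.2)  # 0.5 * 2/5
        # Greenwood by hand: Var(S(4)) = S^2 (5/(10*5) + 3/(5*2))
        assert km.se[2] == pytest.approx(0.2 * math.sqrt(5 / 50 + 3 / 10), rel=1e-12)

    def test_no_detachment_flat_curve(self):
        km = sv.kaplan_meier([_assay((0, 0, 0, 0, 0), 50)])
        np.testing.assert_allclose(km.survival, 1.0)

    def test_total_detachment_first_step(self):
        km = sv.kaplan_meier([_assay((30, 0, 0, 0, 0), 0)])
        assert km.survival[1] == 0.0

    def test_equals_empirical_fraction_without_censoring(self):
        km = sv.kaplan_meier([_assay((10, 20, 30, 25, 15), 0)])
        detached = np.cumsum([10, 20, 30, 25, 15])
        np.testing.assert_allclose(km.survival[1:], 1 - detached / 100.0)

    def test_survival_monotone(self, assays_by_condition):
        for group in assays_by_condition.values():
            km = sv.kaplan_meier(group)
            assert np.all(np.diff(km.survival) <= 0)
            assert km.survival[0] == 1.0

    def test_zero_diaspores_rejected(self):
        with pytest.raises(ValueError):
            sv.kaplan_meier([_assay((0, 0, 0, 0, 0), 0)])

    def test_mixed_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            sv.pool_assays([_assay((1, 1, 1, 1, 1), 5), _assay((1, 1), 5, steps=(2.0, 4.0))])


class TestLogRank:
    def test_identical_groups_null(self):
        g = [_assay((5, 5, 5, 5, 5), 25)]
        chi, df, p = sv.log_rank(g, g)
        assert chi == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, assays_by_condition):
        a, b = assays_by_condition["dry"], assays_by_condition["wet"]
        chi_ab, _, _ = sv.log_rank(a, b)
        chi_ba, _, _ = sv.log_rank(b, a)
        assert chi_ab == pytest.approx(chi_ba, rel=1e-9)

    def test_separated_hazards_detected(self, assays_by_condition):
        # ~3000 diaspores per condition with different detachment thresholds
        chi, df, p = sv.log_rank(assays_by_condition["dry"], assays_by_condition["wet"])
        assert p < 0.001
        assert chi > 100


class TestParametricFamilies:
    def test_gengamma_q1_is_weibull(self, assays_by_condition):
        pooled = sv.pool_assays(assays_by_condition["dry"])
        wb = sv.fit_parametric(pooled, "weibull")
        # analytic nesting: gengamma(mu=ln scale, sigma=1/shape, Q=1)
        gg_params = {
            "mu": math.log(wb.params["scale"]),
            "sigma": 1.0 / wb.params["shape"],
            "Q": 1.0,
        }
        steps, detached, censored = pooled
        ll = sv._interval_loglik(sv.FAMILIES["generalized-gamma"], gg_params, steps, detached, censored)
        assert ll == pytest.approx(wb.loglik, abs=1e-6)

    def test_gengamma_q0_is_lognormal(self):
        u = np.array([0.5, 2.0, 5.0, 9.0, 15.0])
        from scipy.stats import norm

        got = _gengamma_cdf(1.5, 0.6, 0.0, u)
        np.testing.assert_allclose(got, norm.cdf((np.log(u) - 1.5) / 0.6), rtol=1e-9)

    def test_gengamma_nests_every_simpler_family(self, assays_by_condition):
        # the 3-parameter fit can never have lower likelihood than its nested
        # 1- and 2-parameter special cases
        pooled = sv.pool_assays(assays_by_condition["wet"])
        gg = sv.fit_parametric(pooled, "generalized-gamma")
        for fam in ("weibull", "exponential", "log-normal"):
            nested = sv.fit_parametric(pooled, fam)
            assert gg.loglik >= nested.loglik - 1e-4

    def test_generate_and_refit_recovery(self):
        truth = {"mu": 2.0, "sigma": 0.4, "Q": 0.5}
        rng = np.random.default_rng(11)
        speeds = gengamma_rvs(truth["mu"], truth["sigma"], truth["Q"], 5000, rng)
        steps = np.array(STEPS)
        detached = np.array(
            [
                np.sum((speeds > lo) & (speeds <= hi))
                for lo, hi in zip(np.concatenate([[0.0], steps[:-1]]), steps)
            ]
        )
        censored = int(np.sum(speeds > steps[-1]))
        fit = sv.fit_parametric((steps, detached, censored), "generalized-gamma")

        # bootstrap s.e. of each parameter from 40 multinomial resamples
        n = detached.sum() + censored
        probs = np.concatenate([detached, [censored]]) / n
        boots = []
        for _ in range(40):
            counts = rng.multinomial(n, probs)
            bfit = sv.fit_parametric((steps, counts[:-1], int(counts[-1])), "generalized-gamma")
            boots.append([bfit.params["mu"], bfit.params["sigma"], bfit.params["Q"]])
        se = np.std(boots, axis=0, ddof=1)
        est = np.array([fit.params["mu"], fit.params["sigma"], fit.params["Q"]])
        tru = np.array([truth["mu"], truth["sigma"], truth["Q"]])
        assert np.all(np.abs(est - tru) < 3 * np.maximum(se, 1e-3))

    def test_aic_identity_and_penalty(self, assays_by_condition):
        pooled = sv.pool_assays(assays_by_condition["dry"])
        fits = [sv.fit_parametric(pooled, fam) for fam in sv.DEFAULT_FAMILY_SET]
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik, rel=1e-12)
        best, table = sv.select_by_aic(fits)
        assert list(table["aic"]) == sorted(table["aic"])
        assert best.aic == table["aic"].iloc[0]

    def test_exponential_wins_on_exponential_data(self):
        # when the extra gengamma parameters buy < 2 units of log-likelihood,
        # the 2k penalty must favour the exponential
        rng = np.random.default_rng(5)
        speeds = rng.exponential(5.0, size=4000)
        steps = np.array(STEPS)
        detached = np.array(
            [
                np.sum((speeds > lo) & (speeds <= hi))
                for lo, hi in zip(np.concatenate([[0.0], steps[:-1]]), steps)
            ]
        )
        pooled = (steps, detached, int(np.sum(speeds > steps[-1])))
        ex = sv.fit_parametric(pooled, "exponential")
        gg = sv.fit_parametric(pooled, "generalized-gamma")
        if gg.loglik - ex.loglik < 2.0:
            assert ex.aic < gg.aic


def test_gengamma_fit_matches_flexsurv_oracle(tmp_path):
    """The interval-censored generalized-gamma MLE agrees with an
    independent fit of the same counts by R's flexsurv package."""
    import subprocess

    steps = np.array(STEPS)
    detached = np.array([120, 300, 500, 700, 600])
    censored = 800
    ours = sv.fit_parametric((steps, detached, censored), "generalized-gamma")

    script = tmp_path / "gg.R"
    script.write_text(
        """
suppressMessages(library(flexsurv))
steps <- c(2,4,6,8,9.8); lo <- c(0,2,4,6,8)
detached <- c(120,300,500,700,600); cens <- 800
t1 <- c(rep(lo, detached), rep(9.8, cens))
t2 <- c(rep(steps, detached), rep(Inf, cens))
fit <- flexsurvreg(Surv(t1, t2, type="interval2") ~ 1, dist="gengamma")
cat(sprintf("%.10f %.10f %.10f %.8f", fit$res["mu","est"],
    fit$res["sigma","est"], fit$res["Q","est"], fit$loglik))
"""
    )
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    mu, sigma, q, loglik = map(float, proc.stdout.split())
    assert ours.params["mu"] == pytest.approx(mu, abs=1e-4)
    assert ours.params["sigma"] == pytest.approx(sigma, abs=1e-4)
    assert ours.params["Q"] == pytest.approx(q, abs=1e-3)
    assert ours.loglik == pytest.approx(loglik, abs=1e-4)


class TestDetachmentProbability:
    def test_limits_and_monotonicity(self, detach_fits):
        for fit in detach_fits.values():
            assert sv.detachment_probability(0.0, fit) == 0.0
            assert sv.detachment_probability(1e4, fit) == pytest.approx(1.0, abs=1e-6)
            grid = np.asarray(sv.detachment_probability(np.linspace(0, 30, 301), fit))
            assert np.all(np.diff(grid) >= 0)
            assert np.all((grid >= 0) & (grid <= 1))

    def test_extrapolation_beyond_assay_limit(self, detach_fits):
        # the fitted CDF keeps rising above the 9.8 m/s assay ceiling
        fit = detach_fits["wet"]
        assert sv.detachment_probability(15.0, fit) > sv.detachment_probability(9.8, fit)

    def test_negative_speed_rejected(self, detach_fits):
        with pytest.raises(ValueError):
            sv.detachment_probability(-1.0, detach_fits["dry"])
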