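import numpy as np
import pytest
from dataclasses import replace
from scipy import integrate, stats

import mstbayes as mb
from mstbayes.bayes import _Model, _initial_theta, PriorConfig, student_t_logpdf


def hdi_window_oracle(samples, mass):
    """Exhaustive scan over every contiguous sorted window."""
    s = np.sort(np.asarray(samples, float))
    n = s.size
    k = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - k + 1):
        width = s[i + k - 1] - s[i]
        if width < best[0]:
            best = (width, (s[i], s[i + k - 1]))
    return best[1]


class TestStudentT:
    def test_cauchy_peak_closed_form(self):
        assert student_t_logpdf(0.0, 0.0, 1, 1.0) == pytest.approx(np.log(1 / np.pi))

    @pytest.mark.parametrize("nu,lam", [(1, 1.0), (4, 0.3), (30, 5.0)])
    def test_density_integrates_to_one(self, nu, lam):
        val, _ = integrate.quad(lambda x: np.exp(student_t_logpdf(x, 0.7, nu, lam)), -np.inf, np.inf)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_approaches_normal_as_dof_grow(self):
        # monotone convergence of the density to Normal(mu, 1/sqrt(lam))
        # over |x - mu| <= 2 sigma; at dof 30 the gap is ~5%
        sigma = 1.3
        x = np.linspace(-2 * sigma, 2 * sigma, 101)
        norm = stats.norm.pdf(x, 0, sigma)
        gaps = [
            np.max(np.abs(np.exp(student_t_logpdf(x, 0, nu, 1 / sigma**2)) - norm) / norm)
            for nu in (3, 10, 30)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.06

    def test_precision_parameterization_matches_scipy_t(self):
        x = np.linspace(-4, 4, 21)
        for nu, lam in ((2, 0.5), (7, 3.0)):
            ours = student_t_logpdf(x, 0.3, nu, lam)
            ref = stats.t.logpdf(x, nu, loc=0.3, scale=1 / np.sqrt(lam))
            assert np.allclose(ours, ref, rtol=1e-12)


class TestLogLikelihood:
    def test_matches_pointwise_sum(self, clean_dataset):
        theta = dict(kd=500.0, u=800.0, b=780.0, c_fl=50.0, nu=5, lam=1.0)
        ll = mb.log_likelihood(clean_dataset, **theta)
        mu = mb.mass_action_response(
            clean_dataset.concentrations, mb.BindingParams(kd=500.0, u=800.0, b=780.0, c_fl=50.0)
        )
        expected = float(np.sum(student_t_logpdf(clean_dataset.responses, mu, 5, 1.0)))
        assert ll == pytest.approx(expected)

    @pytest.mark.parametrize(
        "override", [{"kd": 0.5}, {"u": 1500.0}, {"lam": 150.0}, {"nu": 31}, {"nu": 2.5}, {"c_fl": -1.0}]
    )
    def test_outside_support_is_minus_inf(self, clean_dataset, override):
        theta = dict(kd=500.0, u=800.0, b=780.0, c_fl=50.0, nu=5, lam=1.0)
        theta.update(override)
        assert mb.log_likelihood(clean_dataset, **theta) == -np.inf


class TestModelGradients:
    def test_analytic_gradient_matches_finite_differences(self, case2_dataset):
        priors = PriorConfig(cfl_mu=50.0)
        m = _Model(case2_dataset.concentrations, case2_dataset.responses, priors)
        z = m.to_z(_initial_theta(case2_dataset, priors)) + 0.05
        for nu in (1, 7, 30):
            _, grad = m.logp_grad(z, nu)
            for j in range(z.size):
                h = 1e-6 * max(1.0, abs(z[j]))
                zp, zm = z.copy(), z.copy()
                zp[j] += h
                zm[j] -= h
                num = (m.logp_grad(zp, nu)[0] - m.logp_grad(zm, nu)[0]) / (2 * h)
                assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestHdi:
    def test_requires_two_samples_and_valid_mass(self):
        with pytest.raises(ValueError):
            mb.hdi([1.0])
        with pytest.raises(ValueError):
            mb.hdi([1.0, 2.0], mass=1.0)

    def test_degenerate_samples_zero_width(self):
        assert mb.hdi([3.0] * 50) == (3.0, 3.0)

    def test_sorted_run_tie_broken_to_first(self):
        lo, hi = mb.hdi(np.arange(1, 101), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).normal(size=100_000)
        lo, hi = mb.hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    @pytest.mark.parametrize("dist", ["normal", "lognormal", "uniform"])
    def test_agrees_with_exhaustive_window_oracle(self, dist, rng):
        draws = getattr(rng, dist)(size=500)
        for mass in (0.5, 0.9, 0.95):
            assert mb.hdi(draws, mass) == pytest.approx(hdi_window_oracle(draws, mass))


class TestFitBayes:
    def test_noiseless_recovery_within_one_percent(self, clean_posterior, clean_params):
        assert clean_posterior.median("kd") == pytest.approx(clean_params.kd_true, rel=0.01)
        assert clean_posterior.median("u") == pytest.approx(clean_params.u_true, rel=0.01)
        assert clean_posterior.median("b") == pytest.approx(clean_params.b_true, rel=0.01)

    def test_all_draws_respect_prior_support(self, case2_posterior):
        priors = case2_posterior.priors
        for name, (lo, hi) in priors.bounds.items():
            draws = case2_posterior.array(name)
            assert np.all(draws > lo) and np.all(draws < hi)
        nu = case2_posterior.array("nu")
        assert np.array_equal(nu, np.round(nu))
        assert nu.min() >= 1 and nu.max() <= 30

    def test_seed_reproducibility(self, clean_dataset):
        cfg = mb.McmcConfig(n_iterations=200, n_tune=150, rng_seed=31)
        a = mb.fit_bayes(clean_dataset, mcmc=cfg)
        b = mb.fit_bayes(clean_dataset, mcmc=cfg)
        assert np.array_equal(a.array("kd"), b.array("kd"))
        assert np.array_equal(a.array("nu"), b.array("nu"))

    def test_flat_signal_posterior_is_prior_dominated(self):
        params = mb.TestCaseParams(
            kd_true=500.0, b_true=800.0, u_true=800.0, noise_sd=1.0, repeats=3, rng_seed=4
        )
        post = mb.fit_bayes(
            mb.generate_dataset(params), mcmc=mb.McmcConfig(n_iterations=1500, n_tune=400, rng_seed=0)
        )
        lo, hi = post.hdi("kd")
        kd_lo, kd_hi = post.priors.kd_bounds
        assert hi - lo > 0.5 * (kd_hi - kd_lo)

    def test_precision_improves_with_repeats(self, fast_mcmc):
        widths = []
        for i, repeats in enumerate((1, 3, 10)):
            params = replace(mb.TABLE_CASES[0], repeats=repeats, rng_seed=50 + i)
            post = mb.fit_bayes(mb.generate_dataset(params), mcmc=fast_mcmc)
            lo, hi = post.hdi("kd")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_two_chains_and_diagnostics(self, clean_dataset):
        cfg = mb.McmcConfig(n_iterations=300, n_tune=200, n_chains=2, rng_seed=1)
        post = mb.fit_bayes(clean_dataset, mcmc=cfg)
        assert post.draws["kd"].shape == (2, 300)
        diag = post.diagnostics()
        assert np.isfinite(diag["kd"]["rhat"])
        assert diag["kd"]["ess"] > 10

    def test_out_of_window_responses_rejected_with_hint(self, clean_dataset):
        shifted = clean_dataset.with_responses(clean_dataset.responses + 5000.0)
        with pytest.raises(ValueError, match="rescale"):
            mb.fit_bayes(shifted)

    def test_rescaling_round_trip(self, clean_dataset, fast_mcmc):
        from mstbayes.bayes import invert_rescaled_summary, rescale_responses

        shifted = clean_dataset.with_responses(clean_dataset.responses * 10 + 4000.0)
        scaled, transform = rescale_responses(shifted)
        post = mb.fit_bayes(scaled, mcmc=fast_mcmc)
        summary = invert_rescaled_summary(post.summary(), transform)
        assert summary["u"]["median"] == pytest.approx(8000 + 4000, rel=0.01)
        assert summary["b"]["median"] == pytest.approx(7800 + 4000, rel=0.01)


class TestCurveSwarm:
    def test_zero_curves_is_empty(self, case2_posterior):
        swarm = mb.posterior_curve_swarm(case2_posterior, 0, [0.0, 100.0])
        assert swarm.shape == (0, 2)

    def test_too_many_curves_rejected(self, case2_posterior):
        with pytest.raises(ValueError):
            mb.posterior_curve_swarm(case2_posterior, 10**7, [100.0])

    def test_curve_at_zero_equals_that_draws_unbound_level(self, case2_posterior):
        # joint draws: the c = 0 intercept must be one of the sampled U values
        swarm = mb.posterior_curve_swarm(case2_posterior, 25, [0.0, 500.0], rng_seed=3)
        u_draws = case2_posterior.array("u")
        for val in swarm[:, 0]:
            assert np.min(np.abs(u_draws - val)) < 1e-9

    def test_tight_posterior_curves_collapse(self, clean_posterior):
        grid = np.geomspace(1.0, 5e4, 40)
        swarm = mb.posterior_curve_swarm(clean_posterior, 10, grid, rng_seed=0)
        spread = np.max(swarm.max(axis=0) - swarm.min(axis=0))
        assert spread < 0.5  # response units; plateaus span 20


class TestCompareAffinities:
    def test_identical_posteriors_give_half(self, case2_posterior):
        result = mb.compare_affinities(case2_posterior, case2_posterior, rng_seed=0)
        assert result.prob_a_less == pytest.approx(0.5, abs=0.05)

    def test_disjoint_supports_give_one(self, rng):
        a = rng.uniform(10, 20, size=2000)
        b = rng.uniform(100, 200, size=2000)
        assert mb.compare_affinities(a, b).prob_a_less == 1.0

    def test_order_of_magnitude_separation_is_decisive(self, rng):
        # synthetic posteriors shaped like two experimental systems:
        # 1.6 uM with HDI 0.72-3.0 vs 80.7 uM with HDI 12.2-398.2
        sd_a = np.log10(3.0 / 0.72) / (2 * 1.96)
        sd_b = np.log10(398.2 / 12.2) / (2 * 1.96)
        a = 10 ** rng.normal(np.log10(1600), sd_a, size=4000)
        b = 10 ** rng.normal(np.log10(80700), sd_b, size=4000)
        result = mb.compare_affinities(a, b, rng_seed=1)
        assert result.prob_a_less > 0.95
        assert result.summary()["log10_ratio_median"] < 0

    def test_empty_rejected(self, case2_posterior):
        with pytest.raises(ValueError):
            mb.compare_affinities(np.array([]), case2_posterior)
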