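"""Monte-Carlo simulation-convolution engine behavior."""

import numpy as np
import pytest
from scipy.stats import norm

import statsmodels.api as sm

from brachyidv import (
    OARRegressionSpec,
    SimulationConfig,
    convolve_response,
    fit_logistic_mle,
    logistic_response,
    response,
    sample_oar_idv,
    simulate_treatments,
    snd_spec,
)
from brachyidv.errors import (
    ConfigurationError,
    ContractError,
    SeparationError,
)


def closed_form_probit_snd(grid, params, sigma_pct, nominal=45.0, physical=44.25):
    """Gaussian IDV convolved with a probit curve has a normal-CDF closed form:
    the delivered dose at nominal prescription P is normal with mean
    ``physical + (P - nominal)`` and SD ``(sigma%/100) * (P - nominal)``."""
    s = params.probit_scale
    hdr = np.asarray(grid) - nominal
    sigma_d = (sigma_pct / 100.0) * hdr
    return norm.cdf((physical + hdr - params.d50) / np.hypot(s, sigma_d))


class TestConfig:
    def test_default_grid_spans_roci(self):
        cfg = SimulationConfig()
        assert cfg.dose_grid[0] == 70.0 and cfg.dose_grid[-1] == 100.0
        assert np.all(np.diff(cfg.dose_grid) == cfg.grid_step)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(roci=(40.0, 100.0))
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_sims_per_dose=10)


class TestSimulateTreatments:
    def test_control_reproduces_reference_probabilities(self, registry, config):
        """No-IDV control: per-dose outcome means match the curve within a
        99.9% binomial interval (the accuracy-testing control)."""
        sim = simulate_treatments(registry["TCP2C"], None, config, refit=False)
        ref = response(config.delivered_control_grid(), registry["TCP2C"])
        se = np.sqrt(ref * (1 - ref) / config.n_sims_per_dose)
        assert np.all(np.abs(sim.outcomes.mean(axis=1) - ref) < 3.3 * se)

    def test_snd_convolution_matches_closed_form_at_85(self, registry, snd):
        cfg = SimulationConfig(n_sims_per_dose=100_000, seed=3)
        sim = simulate_treatments(registry["TCP2C"], snd, cfg, refit=False)
        k = int(np.where(sim.dose_grid == 85.0)[0][0])
        expected = closed_form_probit_snd(85.0, registry["TCP2C"], snd.sd_idv)
        se = np.sqrt(expected * (1 - expected) / cfg.n_sims_per_dose)
        assert sim.outcomes[k].mean() == pytest.approx(float(expected), abs=4 * se)
        assert float(expected) == pytest.approx(0.872, abs=2e-3)

    def test_deterministic_under_seed(self, registry, small_config, snd):
        a = simulate_treatments(registry["TCP2B"], snd, small_config, refit=False)
        b = simulate_treatments(registry["TCP2B"], snd, small_config, refit=False)
        assert np.array_equal(a.outcomes, b.outcomes)

    def test_delivered_doses_floored_at_ebrt(self, registry, small_config, beta_spec):
        sim = simulate_treatments(registry["TCP1"], beta_spec, small_config,
                                  refit=False)
        assert sim.delivered_doses.min() >= small_config.ebrt_eqd2


class TestSampleOARIDV:
    def test_exact_linear_map_without_residual(self, rng):
        spec = OARRegressionSpec("rectum", 0.5, 1.0, 0.0)
        out = sample_oar_idv(np.array([-10.0, 4.0]), spec, rng)
        assert np.allclose(out, [-4.0, 3.0])

    def test_moments(self, rng):
        spec = OARRegressionSpec("rectum", 0.5, 0.0, 8.0)
        out = sample_oar_idv(np.full(100_000, -10.0), spec, rng)
        assert out.mean() == pytest.approx(-5.0, abs=0.1)
        assert out.std() == pytest.approx(8.0, abs=0.1)

    def test_uncorrelated_excluded(self, rng):
        spec = OARRegressionSpec("sigmoid", 0.0, 0.0, 8.0, correlated=False)
        with pytest.raises(ContractError):
            sample_oar_idv(0.0, spec, rng)


class TestLogisticMLE:
    def test_parameter_recovery(self, registry):
        cfg = SimulationConfig(grid_step=1.0, n_sims_per_dose=3226, seed=21)
        sim = simulate_treatments(registry["TCP1"], None, cfg, refit=False)
        # regress against the physically delivered control doses so the
        # generating parameters are exactly recoverable
        doses = np.repeat(cfg.delivered_control_grid(), cfg.n_sims_per_dose)
        fit = fit_logistic_mle(doses, sim.outcomes.ravel())
        assert fit.d50 == pytest.approx(36.0, abs=1.5)
        assert fit.gamma == pytest.approx(0.47, abs=0.05)

    def test_matches_statsmodels_logit(self, registry, small_config):
        """Independent cross-check: identical optimum as a generic GLM fit."""
        sim = simulate_treatments(registry["TCP1"], None, small_config, refit=False)
        doses = np.repeat(sim.dose_grid, small_config.n_sims_per_dose)
        y = sim.outcomes.ravel()
        fit = fit_logistic_mle(doses, y)
        sm_fit = sm.Logit(y, sm.add_constant(doses)).fit(disp=0)
        b0, b1 = sm_fit.params
        assert fit.gamma == pytest.approx(-b0 / 4.0, rel=1e-4)
        assert fit.d50 == pytest.approx(-b0 / b1, rel=1e-4)

    def test_single_class_raises_separation(self):
        with pytest.raises(SeparationError):
            fit_logistic_mle(np.linspace(70, 100, 50), np.ones(50))

    def test_complete_separation_detected(self):
        doses = np.linspace(70.0, 100.0, 200)
        outcomes = (doses > 85.0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic_mle(doses, outcomes)

    def test_shuffle_invariance(self, registry, small_config, rng):
        sim = simulate_treatments(registry["TCP1"], None, small_config, refit=False)
        doses = np.repeat(sim.dose_grid, small_config.n_sims_per_dose)
        y = sim.outcomes.ravel().astype(float)
        perm = rng.permutation(doses.size)
        fit1 = fit_logistic_mle(doses, y)
        fit2 = fit_logistic_mle(doses[perm], y[perm])
        assert fit1.d50 == pytest.approx(fit2.d50, rel=1e-6)
        assert fit1.gamma == pytest.approx(fit2.gamma, rel=1e-6)


class TestConvolveResponse:
    def test_point_mass_identity(self, registry, config):
        out = convolve_response(registry["TCP2C"], None, config)
        assert np.allclose(out, response(config.delivered_control_grid(),
                                         registry["TCP2C"]))

    def test_probit_normal_closed_form(self, registry, config, snd):
        for name in ("TCP2A", "TCP2B", "TCP2C", "NTCP_ref"):
            out = convolve_response(registry[name], snd, config)
            oracle = closed_form_probit_snd(config.dose_grid, registry[name],
                                            snd.sd_idv)
            assert np.allclose(out, oracle, atol=1e-3)

    def test_quadrature_matches_monte_carlo(self, registry, config, beta_spec):
        quad = convolve_response(registry["TCP2B"], beta_spec, config)
        sim = simulate_treatments(registry["TCP2B"], beta_spec,
                                  SimulationConfig(n_sims_per_dose=100_000, seed=5),
                                  refit=False)
        mc = sim.outcomes.mean(axis=1)
        se = np.sqrt(quad * (1 - quad) / 100_000)
        assert np.all(np.abs(mc - quad) < 3.5 * se)

    def test_zero_noise_refit_reproduces_logistic_reference(self, registry, config):
        """Control pipeline, model-form-correct case: refit R' tracks R
        within Monte-Carlo error."""
        sim = simulate_treatments(registry["TCP1"], None, config)
        ref = logistic_response(config.delivered_control_grid(), registry["TCP1"])
        se = np.sqrt(ref * (1 - ref) / config.n_sims_per_dose)
        assert np.all(np.abs(sim.rprime_curve - ref) < 3 * se)
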