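"""Failure-rate statistics, curve differences, and dose-escalation logic."""

import numpy as np
import pytest

from brachyidv import (
    FailureRateResult,
    SimulationConfig,
    combined_oar_curve,
    compare_rates_ttest,
    convolve_response,
    dose_escalation_estimate,
    failure_rate,
    lc_difference,
    replicate_failure_rates,
    response,
    sigma_distance,
    simulate_treatments,
)
from brachyidv.errors import GridError, InvalidInputError
from brachyidv.simulation import SimulationResult


def _result_from_outcomes(outcomes):
    outcomes = np.atleast_2d(np.asarray(outcomes, dtype=np.int8))
    return SimulationResult(
        dose_grid=np.arange(outcomes.shape[0], dtype=float),
        outcomes=outcomes, refit_params=None, rprime_curve=None,
    )


def test_failure_rate_direct_counts():
    assert failure_rate(_result_from_outcomes([[1, 1, 1, 1]])) == 0.0
    assert failure_rate(_result_from_outcomes([[1, 0, 1, 0]])) == 50.0


def test_control_failure_rate_matches_grid_mean_oracle(registry, small_config):
    """Pooled control failure equals the grid mean of 1 - R(D)."""
    sim = simulate_treatments(registry["TCP2B"], None, small_config, refit=False)
    expected = 100.0 * np.mean(
        1.0 - response(small_config.delivered_control_grid(), registry["TCP2B"]))
    n_total = sim.outcomes.size
    se = 100.0 * np.sqrt(0.25 / n_total)  # conservative binomial SE
    assert failure_rate(sim) == pytest.approx(expected, abs=5 * se)


def test_replicate_statistics_and_reproducibility(registry, small_config):
    res = replicate_failure_rates(registry["TCP2A"], None, small_config)
    res2 = replicate_failure_rates(registry["TCP2A"], None, small_config)
    assert res.replicate_rates == res2.replicate_rates
    assert len(res.replicate_rates) == small_config.n_replicates
    assert res.sd_rate > 0


def test_replicate_sd_scales_with_simulation_size(registry):
    """Replicate SD shrinks like 1/sqrt(n_sims) across a 4x sweep."""
    sds = []
    for n in (2500, 10_000):
        cfg = SimulationConfig(n_sims_per_dose=n, n_replicates=20, seed=31)
        sds.append(replicate_failure_rates(registry["TCP2C"], None, cfg).sd_rate)
    ratio = sds[0] / sds[1]
    assert ratio == pytest.approx(2.0, rel=0.3)


def test_sigma_distance_hand_arithmetic():
    control = FailureRateResult("TCP2C", "control", (16.1,) * 3, 16.1, 0.06)
    test = FailureRateResult("TCP2C", "beta", (17.9,) * 3, 17.9, 0.08)
    out = sigma_distance(test, control)
    assert out.sigma_from_control == pytest.approx((17.9 - 16.1) / 0.06)
    assert out.sigma_from_control == pytest.approx(30.0, abs=0.01)


class TestWelch:
    def test_identical_vectors(self):
        assert compare_rates_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_samples(self, rng):
        a = rng.normal(17.9, 0.08, 30)
        b = rng.normal(17.0, 0.07, 30)
        assert compare_rates_ttest(a, b) < 1e-3

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 20)
        assert compare_rates_ttest(a, b) == pytest.approx(compare_rates_ttest(b, a))

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.05 over 1,000 simulations."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(16.0, 0.06, 30)
            b = rng.normal(16.0, 0.06, 30)
            rejections += compare_rates_ttest(a, b) < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_degenerate_input_guards(self):
        with pytest.raises(InvalidInputError):
            compare_rates_ttest([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            compare_rates_ttest([1.0, 1.0], [2.0, 2.0])


class TestLCDifference:
    def test_zero_when_curves_equal(self, registry, config):
        grid = config.dose_grid
        ref = response(grid, registry["TCP2C"])
        assert lc_difference(ref, registry["TCP2C"], 85.0, grid) == pytest.approx(0.0)

    def test_snd_quadrature_reduction_at_85(self, registry, config, snd):
        """Gaussian IDVs reduce the TCP2C local-control probability at a
        nominal 85 Gy by about 2.3 percentage points relative to the
        published reference curve (closed-form value -2.26)."""
        rprime = convolve_response(registry["TCP2C"], snd, config)
        diff = lc_difference(rprime, registry["TCP2C"], 85.0, config.dose_grid)
        assert diff == pytest.approx(-2.26, abs=0.15)

    def test_reduction_grows_with_idv_spread(self, registry, config):
        from brachyidv import snd_spec

        diffs = []
        for sd in (5.0, 11.2, 20.0):
            rprime = convolve_response(registry["TCP2C"], snd_spec(sd), config)
            diffs.append(lc_difference(rprime, registry["TCP2C"], 85.0,
                                       config.dose_grid))
        assert diffs[0] > diffs[1] > diffs[2]  # increasingly negative

    def test_out_of_grid_dose(self, registry, config):
        ref = response(config.dose_grid, registry["TCP2C"])
        with pytest.raises(GridError):
            lc_difference(ref, registry["TCP2C"], 120.0, config.dose_grid)


class TestCombinedOAR:
    def test_pointwise_mean(self):
        combined = combined_oar_curve([[0.2, 0.4], [0.4, 0.6]])
        assert np.allclose(combined, [0.3, 0.5])

    def test_identity_and_bounds(self, rng):
        curves = [rng.uniform(0, 1, 10) for _ in range(3)]
        combined = combined_oar_curve(curves)
        assert np.all(combined <= np.max(curves, axis=0) + 1e-12)
        assert np.all(combined >= np.min(curves, axis=0) - 1e-12)
        assert np.allclose(combined_oar_curve([curves[0]]), curves[0])

    def test_mismatched_grids(self):
        with pytest.raises(GridError):
            combined_oar_curve([[0.1, 0.2], [0.1, 0.2, 0.3]])


class TestDoseEscalation:
    def test_constructed_shift(self, registry, config):
        grid = np.arange(70.0, 100.5, 0.5)
        ref = response(grid, registry["NTCP_ref"])
        shifted = response(grid - 10.0 + 10.0, registry["NTCP_ref"])  # identity
        assert dose_escalation_estimate(ref, shifted, 80.0, grid) == pytest.approx(0.0)
        shifted_right = response(grid - 10.0, registry["NTCP_ref"])
        assert dose_escalation_estimate(ref, shifted_right, 80.0, grid) == pytest.approx(
            10.0, abs=1e-6
        )

    def test_positive_escalation_under_reducing_convolution(self, registry, config):
        """An IDV distribution with negative mean shifts the complication
        curve down, opening positive dose-escalation headroom."""
        grid = np.arange(70.0, 100.5, 0.5)
        ref = response(grid, registry["NTCP_ref"])
        from brachyidv import beta_from_moments

        wide = beta_from_moments(-5.0, 15.0, -0.6, 10.0)
        rprime = convolve_response(registry["NTCP_ref"], wide, config, grid=grid)
        assert dose_escalation_estimate(ref, rprime, 80.0, grid) > 0

    def test_unbracketed_level(self, registry):
        grid = np.arange(70.0, 100.5, 0.5)
        ref = response(grid, registry["NTCP_ref"])
        with pytest.raises(GridError):
            dose_escalation_estimate(ref, ref * 0.0 + 0.9, 80.0, grid)
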