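"""Treatment-failure rates, replicate statistics, and curve comparisons.

The event simulator's binary outcomes are pooled over the dose grid into a
3-year treatment failure rate (percent of non-responses).  Each sampling
condition (control / Beta / normal IDVs) is repeated over independent
replicates; test conditions are located relative to the control by
sigma-distance (difference of means in control replicate SDs) and compared
across conditions by Welch's t-test.  Convolved-vs-reference probability
differences, the combined organ-at-risk complication curve, and the
iso-complication dose-escalation estimate live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from brachyidv.cohort import OARRegressionSpec
from brachyidv.errors import GridError, InvalidInputError
from brachyidv.idv import IDVDistributionSpec
from brachyidv.radiobiology import DoseResponseParams, response
from brachyidv.simulation import SimulationConfig, SimulationResult, simulate_treatments


@dataclass(frozen=True)
class FailureRateResult:
    """Replicate failure-rate statistics for one curve under one sampling mode."""

    curve_name: str
    sampling: str  # "control", "beta", "normal", ...
    replicate_rates: tuple[float, ...]
    mean_rate: float
    sd_rate: float
    sigma_from_control: float | None = None


def failure_rate(result: SimulationResult) -> float:
    """Percent of simulated non-responses, pooled over the full dose grid."""
    outcomes = np.asarray(result.outcomes)
    if outcomes.size == 0:
        raise InvalidInputError("empty outcome matrix")
    return float(100.0 * np.mean(outcomes == 0))


def replicate_failure_rates(
    curve: DoseResponseParams,
    idv_spec: IDVDistributionSpec | None,
    config: SimulationConfig,
    *,
    oar_spec: OARRegressionSpec | None = None,
    seed=None,
) -> FailureRateResult:
    """Mean and SD of the pooled failure rate over independent replicates.

    Each replicate draws fresh IDVs and outcomes from a child random
    stream spawned off ``seed`` (or ``config.seed``), so replicates are
    independent yet the whole set is reproducible.
    """
    if config.n_replicates < 2:
        raise InvalidInputError("need at least 2 replicates")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rates = []
    for child in ss.spawn(config.n_replicates):
        rng = np.random.default_rng(child)
        sim = simulate_treatments(curve, idv_spec, config, oar_spec=oar_spec,
                                  rng=rng, refit=False)
        rates.append(failure_rate(sim))
    rates = tuple(rates)
    sampling = "control" if idv_spec is None else idv_spec.family
    return FailureRateResult(
        curve_name=curve.name, sampling=sampling, replicate_rates=rates,
        mean_rate=float(np.mean(rates)), sd_rate=float(np.std(rates, ddof=1)),
    )


def sigma_distance(test: FailureRateResult,
                   control: FailureRateResult) -> FailureRateResult:
    """Distance of the test mean from the control mean, in control replicate
    SDs; returns the test result with ``sigma_from_control`` filled in."""
    if control.sd_rate == 0:
        raise InvalidInputError("control replicate SD is zero")
    sigma = (test.mean_rate - control.mean_rate) / control.sd_rate
    return replace(test, sigma_from_control=float(sigma))


def compare_rates_ttest(rates_a, rates_b) -> float:
    """Welch (unequal-variance) two-sample t-test p-value."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each replicate vector needs length >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise InvalidInputError("zero variance in both replicate vectors")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def lc_difference(rprime: np.ndarray, reference_curve: DoseResponseParams,
                  dose: float, grid: np.ndarray) -> float:
    """Convolved-minus-reference response difference at ``dose``, in
    percentage points; R' is interpolated linearly on the grid."""
    grid = np.asarray(grid, dtype=float)
    if dose < grid.min() or dose > grid.max():
        raise GridError(f"dose {dose} outside grid [{grid.min()}, {grid.max()}]")
    rp = float(np.interp(dose, grid, np.asarray(rprime, dtype=float)))
    return 100.0 * (rp - float(response(dose, reference_curve)))


def combined_oar_curve(structure_curves) -> np.ndarray:
    """Pointwise mean of per-structure complication curves on a shared grid."""
    curves = [np.asarray(c, dtype=float) for c in structure_curves]
    if not curves:
        raise InvalidInputError("no curves given")
    n = curves[0].size
    if any(c.size != n for c in curves):
        raise GridError("curves are on mismatched grids")
    return np.mean(curves, axis=0)


def dose_escalation_estimate(reference_ntcp: np.ndarray, oar_rprime: np.ndarray,
                             base_dose: float, grid: np.ndarray) -> float:
    """Iso-complication dose escalation, Gy.

    The complication level of the reference curve at ``base_dose`` is
    located on the (reduced) convolved OAR curve; the difference between
    that iso-complication dose and ``base_dose`` is the headroom for target
    dose escalation.  Both curves must be non-decreasing over the grid for
    the level to be invertible.
    """
    grid = np.asarray(grid, dtype=float)
    ref = np.asarray(reference_ntcp, dtype=float)
    rp = np.asarray(oar_rprime, dtype=float)
    if ref.size != grid.size or rp.size != grid.size:
        raise GridError("curves and grid have mismatched lengths")
    if base_dose < grid.min() or base_dose > grid.max():
        raise GridError("base_dose outside grid")
    level = float(np.interp(base_dose, grid, ref))
    if level < rp.min() or level > rp.max():
        raise GridError("iso-complication level not bracketed by the grid")
    # invert the monotone convolved curve at the level
    iso_dose = float(np.interp(level, rp, grid))
    return iso_dose - base_dose
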