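"""Synthetic cervical-cancer HDR brachytherapy cohort generator.

Stands in for the institutional 100-patient dataset: HDR prescription EQD2
drawn from a truncated normal (mean 29.4 Gy, SD 7.44 Gy, range 18.8-40 Gy,
alpha/beta = 10), target (HRCTV D90) delivered EQD2 perturbed by an IDV
drawn from a configurable uncertainty distribution, and organ-at-risk
(rectum/bladder/sigmoid D2cc, alpha/beta = 3) IDVs generated through linear
regressions on the target IDV — rectum and bladder correlated, sigmoid
independent — with normal residual scatter.

The regression defaults (slopes, residual SDs, the OAR expected-dose
fraction) are package placeholders for unpublished institutional fits and
are fully configurable; downstream analyses depend only on the
correlated/uncorrelated structure, not on the particular coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import truncnorm

from brachyidv.errors import ConfigurationError, InvalidInputError
from brachyidv.idv import IDVDistributionSpec, compute_idv, sample_idv

#: Cohort prescription statistics (Gy EQD2, alpha/beta = 10).
PRESCRIPTION_MEAN = 29.4
PRESCRIPTION_SD = 7.44
PRESCRIPTION_RANGE = (18.8, 40.0)
#: HRCTV volume statistics (cm^3), carried as metadata only.
VOLUME_MEAN = 53.0
VOLUME_SD = 34.3
#: Expected OAR EQD2 as a fraction of the HRCTV prescription (configurable).
DEFAULT_OAR_DOSE_FRACTION = 0.65

OAR_STRUCTURES = ("rectum", "bladder", "sigmoid")


@dataclass(frozen=True)
class OARRegressionSpec:
    """Linear model of an OAR IDV on the target IDV (percent scale).

    ``oar_idv = slope * hrctv_idv + intercept + N(0, residual_sd)``.
    ``correlated=False`` marks structures whose IDVs show no significant
    regression on the target IDV; such structures are excluded from
    uncertainty sampling and carry slope 0.
    """

    structure: str
    slope: float
    intercept: float
    residual_sd: float
    correlated: bool = True
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise InvalidInputError("residual_sd must be non-negative")
        if not self.correlated and self.slope != 0.0:
            object.__setattr__(self, "slope", 0.0)


def default_oar_specs() -> list[OARRegressionSpec]:
    """Default generator regressions: rectum/bladder moderately correlated
    with the target IDV, sigmoid uncorrelated."""
    return [
        OARRegressionSpec("rectum", 0.5, 0.0, 8.0, correlated=True),
        OARRegressionSpec("bladder", 0.4, 0.0, 8.0, correlated=True),
        OARRegressionSpec("sigmoid", 0.0, 0.0, 8.0, correlated=False),
    ]


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: course-level prescribed/expected and delivered
    EQD2 per structure, plus target volume metadata."""

    patient_id: str
    hrctv_prescribed_eqd2: float
    hrctv_delivered_eqd2: float
    oar_expected_eqd2: dict[str, float]
    oar_delivered_eqd2: dict[str, float]
    hrctv_volume_cc: float

    def __post_init__(self) -> None:
        doses = [self.hrctv_prescribed_eqd2, self.hrctv_delivered_eqd2,
                 *self.oar_expected_eqd2.values(), *self.oar_delivered_eqd2.values()]
        if any(d <= 0 for d in doses):
            raise InvalidInputError("all doses must be positive")


def generate_cohort(
    n_patients: int,
    hrctv_idv_spec: IDVDistributionSpec,
    oar_specs: Sequence[OARRegressionSpec],
    seed=None,
    *,
    prescription_mean: float = PRESCRIPTION_MEAN,
    prescription_sd: float = PRESCRIPTION_SD,
    prescription_range: tuple[float, float] = PRESCRIPTION_RANGE,
    oar_dose_fraction: float = DEFAULT_OAR_DOSE_FRACTION,
) -> list[PatientRecord]:
    """Generate a synthetic cohort, reproducible under ``seed``.

    Prescriptions are truncated-normal on ``prescription_range``; the
    delivered target EQD2 is ``prescribed * (1 + IDV/100)`` with the IDV
    drawn from ``hrctv_idv_spec``; each OAR's expected EQD2 is
    ``oar_dose_fraction * prescribed`` and its delivered EQD2 follows the
    structure's regression spec.
    """
    if n_patients < 1:
        raise InvalidInputError("n_patients must be >= 1")
    if not oar_specs:
        raise ConfigurationError("at least one OAR regression spec is required")
    rng = np.random.default_rng(seed)
    lo, hi = prescription_range
    a = (lo - prescription_mean) / prescription_sd
    b = (hi - prescription_mean) / prescription_sd
    prescribed = truncnorm.rvs(a, b, loc=prescription_mean,
                               scale=prescription_sd, size=n_patients,
                               random_state=rng)
    hrctv_idv = sample_idv(hrctv_idv_spec, n_patients, seed=rng)
    delivered = prescribed * (1.0 + hrctv_idv / 100.0)
    # lognormal volumes matched to the cohort mean/SD
    sigma2 = np.log(1.0 + (VOLUME_SD / VOLUME_MEAN) ** 2)
    volumes = rng.lognormal(np.log(VOLUME_MEAN) - sigma2 / 2.0,
                            np.sqrt(sigma2), size=n_patients)

    oar_idvs = {}
    for spec in oar_specs:
        noise = rng.normal(0.0, spec.residual_sd, size=n_patients)
        oar_idvs[spec.structure] = spec.slope * hrctv_idv + spec.intercept + noise

    cohort = []
    for i in range(n_patients):
        expected = {s.structure: oar_dose_fraction * prescribed[i] for s in oar_specs}
        deliv_oar = {
            s.structure: expected[s.structure] * (1.0 + oar_idvs[s.structure][i] / 100.0)
            for s in oar_specs
        }
        cohort.append(PatientRecord(
            patient_id=f"P{i + 1:04d}",
            hrctv_prescribed_eqd2=float(prescribed[i]),
            hrctv_delivered_eqd2=float(delivered[i]),
            oar_expected_eqd2=expected,
            oar_delivered_eqd2=deliv_oar,
            hrctv_volume_cc=float(volumes[i]),
        ))
    return cohort


def cohort_idv_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient IDVs (percent) for the target and each OAR structure."""
    if not cohort:
        raise InvalidInputError("cohort is empty")
    data = {"hrctv": [
        compute_idv(p.hrctv_delivered_eqd2, p.hrctv_prescribed_eqd2)
        for p in cohort
    ]}
    for structure in cohort[0].oar_expected_eqd2:
        data[structure] = [
            compute_idv(p.oar_delivered_eqd2[structure], p.oar_expected_eqd2[structure])
            for p in cohort
        ]
    return pd.DataFrame(data, index=[p.patient_id for p in cohort])


def fit_oar_regressions(idv_table: pd.DataFrame,
                        alpha: float = 0.05) -> list[OARRegressionSpec]:
    """OLS of each OAR IDV on the target IDV; a structure is flagged
    ``correlated`` when its slope p-value is below ``alpha``.

    Uncorrelated structures are excluded from uncertainty sampling
    downstream.
    """
    if len(idv_table) < 10:
        raise InvalidInputError("need at least 10 patients")
    x = idv_table["hrctv"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise InvalidInputError("degenerate predictor: target IDVs are constant")
    X = sm.add_constant(x)
    specs = []
    for structure in idv_table.columns:
        if structure == "hrctv":
            continue
        y = idv_table[structure].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        p = float(fit.pvalues[1])
        correlated = p < alpha
        specs.append(OARRegressionSpec(
            structure=structure,
            slope=float(fit.params[1]) if correlated else 0.0,
            intercept=float(fit.params[0]),
            residual_sd=float(np.std(fit.resid, ddof=2)),
            correlated=correlated,
            p_value=p,
        ))
    return specs


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Long-format cohort table: one row per patient per structure."""
    rows = []
    for p in cohort:
        rows.append({
            "patient_id": p.patient_id, "structure": "hrctv",
            "prescribed_or_expected_eqd2": p.hrctv_prescribed_eqd2,
            "delivered_eqd2": p.hrctv_delivered_eqd2,
            "idv_percent": compute_idv(p.hrctv_delivered_eqd2, p.hrctv_prescribed_eqd2),
            "hrctv_volume_cc": p.hrctv_volume_cc,
        })
        for structure in p.oar_expected_eqd2:
            rows.append({
                "patient_id": p.patient_id, "structure": structure,
                "prescribed_or_expected_eqd2": p.oar_expected_eqd2[structure],
                "delivered_eqd2": p.oar_delivered_eqd2[structure],
                "idv_percent": compute_idv(p.oar_delivered_eqd2[structure],
                                           p.oar_expected_eqd2[structure]),
                "hrctv_volume_cc": p.hrctv_volume_cc,
            })
    return pd.DataFrame(rows)
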