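"""EQD2 dose arithmetic and reference logistic/probit dose-response curves.

Dose-response is expressed on the total EQD2 scale (external beam plus HDR
brachytherapy).  Two standard sigmoid forms are supported, both parameterized
by the dose of 50% response ``D50`` and the normalized steepness ``gamma``
(slope at D50 expressed per unit relative dose):

* logistic:  ``R(D) = 1 / (1 + exp(4*gamma*(1 - D/D50)))``
* probit:    ``R(D) = Phi((D - D50) * gamma * sqrt(2*pi) / D50)``

The registry holds the five published cervical-cancer reference curves used
throughout the analysis: four tumor-control curves (TCP1 from the
retroEMBRACE pooled cohort; TCP2A/TCP2B/TCP2C for increasing tumor size /
poorer external-beam response) and one rectum/bladder late-morbidity NTCP
curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy.stats import norm

from brachyidv.errors import FormMismatchError, InvalidInputError

#: Nominal EBRT prescription, Gy.  Total prescription doses on the
#: 70-100 Gy range of clinical interest are labeled as this nominal 45 Gy
#: external-beam course plus the 25-55 Gy HDR EQD2 prescription.
EBRT_NOMINAL_EQD2 = 45.0

#: Physical EQD2 of the 45 Gy / 25-fraction (1.8 Gy/fraction) external-beam
#: course under the linear-quadratic model with alpha/beta = 10 Gy:
#: ``45 * (1.8 + 10) / (2 + 10) = 44.25`` Gy.  This is the term actually
#: added to the delivered dose when evaluating dose-response curves.
EBRT_PHYSICAL_EQD2 = 44.25

Form = Literal["logistic", "probit"]
Role = Literal["tumor", "normal_tissue"]


@dataclass(frozen=True)
class DoseResponseParams:
    """A named sigmoid dose-response curve on the total-EQD2 axis.

    Parameters
    ----------
    name : str
        Curve identifier (e.g. ``"TCP2C"``).
    form : {"logistic", "probit"}
        Functional form of the sigmoid.
    d50 : float
        Dose of 50% response, Gy EQD2.  Must be positive.
    gamma : float
        Dimensionless normalized steepness. Must be positive.
    role : {"tumor", "normal_tissue"}
        Whether the curve models tumor control or normal-tissue complication.
    """

    name: str
    form: Form
    d50: float
    gamma: float
    role: Role = "tumor"

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise InvalidInputError(f"D50 must be positive, got {self.d50}")
        if self.gamma <= 0:
            raise InvalidInputError(f"gamma must be positive, got {self.gamma}")
        if self.form not in ("logistic", "probit"):
            raise InvalidInputError(f"unknown form {self.form!r}")
        if self.role not in ("tumor", "normal_tissue"):
            raise InvalidInputError(f"unknown role {self.role!r}")

    @property
    def probit_scale(self) -> float:
        """Normal-CDF scale ``s = D50 / (gamma * sqrt(2*pi))`` in Gy."""
        return self.d50 / (self.gamma * np.sqrt(2.0 * np.pi))


def eqd2(total_dose, dose_per_fraction, alpha_beta) -> np.ndarray | float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    ``EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)`` for a course of total
    dose ``D`` delivered in fractions of size ``d`` to tissue with
    fractionation sensitivity ``alpha_beta`` (Gy; typically 10 for tumor
    targets and 3 for late-responding normal tissue).
    """
    D = np.asarray(total_dose, dtype=float)
    d = np.asarray(dose_per_fraction, dtype=float)
    ab = np.asarray(alpha_beta, dtype=float)
    if np.any(D <= 0) or np.any(d <= 0) or np.any(ab <= 0):
        raise InvalidInputError("eqd2 arguments must all be positive")
    out = D * (d + ab) / (2.0 + ab)
    return out if out.ndim else float(out)


def _clamped(dose) -> np.ndarray:
    D = np.asarray(dose, dtype=float)
    if np.any(~np.isfinite(D)):
        raise InvalidInputError("dose must be finite")
    return np.maximum(D, 0.0)


def logistic_response(dose, params: DoseResponseParams):
    """Logistic dose response ``1 / (1 + exp(4*gamma*(1 - D/D50)))``.

    Doses are clamped at 0 Gy before evaluation.
    """
    if params.form != "logistic":
        raise FormMismatchError(
            f"{params.name} has form {params.form!r}, expected 'logistic'"
        )
    D = _clamped(dose)
    out = 1.0 / (1.0 + np.exp(4.0 * params.gamma * (1.0 - D / params.d50)))
    return out if out.ndim else float(out)


def probit_response(dose, params: DoseResponseParams):
    """Probit dose response ``Phi((D - D50)/s)`` with ``s = D50/(gamma*sqrt(2*pi))``."""
    if params.form != "probit":
        raise FormMismatchError(
            f"{params.name} has form {params.form!r}, expected 'probit'"
        )
    D = _clamped(dose)
    out = norm.cdf((D - params.d50) / params.probit_scale)
    return out if out.ndim else float(out)


def response(dose, params: DoseResponseParams):
    """Evaluate a curve with whichever form it declares."""
    if params.form == "logistic":
        return logistic_response(dose, params)
    return probit_response(dose, params)


# Published reference parameters: (form, D50 [Gy EQD2], gamma, role).
# Form assignment is the package default and can be overridden per curve.
_REFERENCE_TABLE: tuple[tuple[str, Form, float, float, Role], ...] = (
    ("TCP1", "logistic", 36.0, 0.47, "tumor"),
    ("TCP2A", "probit", 45.0, 0.60, "tumor"),
    ("TCP2B", "probit", 61.0, 1.10, "tumor"),
    ("TCP2C", "probit", 68.0, 2.00, "tumor"),
    ("NTCP_ref", "probit", 110.0, 2.00, "normal_tissue"),
)


def reference_registry(
    form_overrides: Mapping[str, Form] | None = None,
) -> dict[str, DoseResponseParams]:
    """The five published reference curves, keyed by name.

    Parameters
    ----------
    form_overrides : mapping, optional
        ``{curve_name: form}`` replacing the default form assignment
        (TCP1 logistic; TCP2A/TCP2B/TCP2C and NTCP_ref probit).
    """
    overrides = dict(form_overrides or {})
    registry: dict[str, DoseResponseParams] = {}
    for name, form, d50, gamma, role in _REFERENCE_TABLE:
        params = DoseResponseParams(name, form, d50, gamma, role)
        if name in overrides:
            params = replace(params, form=overrides.pop(name))
        registry[name] = params
    if overrides:
        raise InvalidInputError(f"unknown curve names in overrides: {sorted(overrides)}")
    return registry


def registry_to_json(registry: Iterable[DoseResponseParams] | Mapping[str, DoseResponseParams]) -> str:
    """Serialize a registry (mapping or iterable of curves) to JSON."""
    if isinstance(registry, Mapping):
        registry = registry.values()
    records = [
        {"name": p.name, "form": p.form, "D50": p.d50, "gamma": p.gamma, "role": p.role}
        for p in registry
    ]
    return json.dumps(records, indent=2)
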