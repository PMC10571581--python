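"""Convolve dose-response curves with IDV uncertainty distributions.

Computes the IDV-convolved tumor-control curves R' through both the
clinical trail (event simulation + logistic MLE refit) and the direct quadrature
expectation, reports local-control probability differences at 85 Gy, builds
the organ-at-risk R' complication curves via regression-derived IDV
sampling (rectum, bladder; sigmoid stays at its reference), combines them,
and estimates the iso-complication dose-escalation headroom from 80 Gy.

Writes results/lc_differences.csv, results/rprime_curves.csv,
results/oar_rprime.csv and results/dose_escalation.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from brachyidv import (
    SimulationConfig,
    combined_oar_curve,
    convolve_response,
    default_beta_spec,
    default_oar_specs,
    dose_escalation_estimate,
    lc_difference,
    reference_registry,
    response,
    simulate_treatments,
    snd_spec,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 20231005
config = SimulationConfig(seed=SEED)
registry = reference_registry()
modes = {"beta": default_beta_spec(), "snd": snd_spec()}

# --- target curves: refit and quadrature R' with LC differences at 85 Gy
lc_rows, curve_rows = [], []
for name in ("TCP1", "TCP2A", "TCP2B", "TCP2C"):
    for mode, spec in modes.items():
        sim = simulate_treatments(registry[name], spec, config)
        quad = convolve_response(registry[name], spec, config)
        grid = sim.dose_grid
        lc_rows.append({
            "curve": name, "sampling": mode,
            "lc_diff_85Gy_refit_pct": lc_difference(
                sim.rprime_curve, registry[name], 85.0, grid),
            "lc_diff_85Gy_quadrature_pct": lc_difference(
                quad, registry[name], 85.0, grid),
            "refit_D50": sim.refit_params.d50,
            "refit_gamma": sim.refit_params.gamma,
        })
        for dose, r_ref, r_fit, r_quad in zip(
                grid, response(grid, registry[name]), sim.rprime_curve, quad):
            curve_rows.append({
                "curve": name, "sampling": mode, "dose_gy": dose,
                "reference": r_ref, "rprime_refit": r_fit,
                "rprime_quadrature": r_quad,
            })

lc = pd.DataFrame(lc_rows)
lc.to_csv(OUT / "lc_differences.csv", index=False)
pd.DataFrame(curve_rows).to_csv(OUT / "rprime_curves.csv", index=False)
print("local-control probability differences at 85 Gy (percentage points):")
print(lc.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# --- organ-at-risk curves: convolve the reference NTCP with regression-derived
#     IDVs for the correlated structures; the uncorrelated sigmoid keeps its
#     reference curve
grid = np.arange(70.0, 100.5, 0.5)
ntcp_ref = response(grid, registry["NTCP_ref"])
# no-IDV control through the same delivery model (physical EBRT term),
# isolating the IDV contribution from the fixed protocol shift
ntcp_control = convolve_response(registry["NTCP_ref"], None, config, grid=grid)
beta = default_beta_spec()
oar_curves, oar_rows = [], []
for spec in default_oar_specs():
    if spec.correlated:
        curve = convolve_response(registry["NTCP_ref"], beta, config,
                                  oar_spec=spec, grid=grid, seed=SEED)
    else:
        curve = ntcp_ref
    oar_curves.append(curve)
    oar_rows.append(pd.DataFrame({
        "structure": spec.structure, "dose_gy": grid, "ntcp_rprime": curve,
    }))
combined = combined_oar_curve(oar_curves)
oar_rows.append(pd.DataFrame({
    "structure": "combined", "dose_gy": grid, "ntcp_rprime": combined}))
pd.concat(oar_rows).to_csv(OUT / "oar_rprime.csv", index=False)

escalation = dose_escalation_estimate(ntcp_ref, combined, 80.0, grid)
summary = {
    "combined_oar_reduction_vs_reference_75Gy_pct": float(
        100 * (np.interp(75.0, grid, ntcp_ref) - np.interp(75.0, grid, combined))),
    "combined_oar_reduction_vs_reference_90Gy_pct": float(
        100 * (np.interp(90.0, grid, ntcp_ref) - np.interp(90.0, grid, combined))),
    "combined_oar_reduction_idv_only_90Gy_pct": float(
        100 * (np.interp(90.0, grid, ntcp_control) - np.interp(90.0, grid, combined))),
    "iso_complication_escalation_from_80Gy_gy": float(escalation),
}
(OUT / "dose_escalation.json").write_text(json.dumps(summary, indent=2) + "\n")
print("\ncombined-OAR morbidity reductions and escalation headroom:")
print(json.dumps(summary, indent=2))
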