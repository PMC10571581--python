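"""Utility model: risk-free local control and the optimal dose.

The utility of a treatment at dose D is ``U(D) = TCP(D) * (1 - NTCP(D))``,
the probability of achieving local control without a complication
(risk-free local control, RFLC).  The dose maximizing U is the predicted
optimal prescription.  Utilities are evaluated for the reference curves and
for the IDV-convolved curves R'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from brachyidv.errors import GridError, InvalidInputError
from brachyidv.radiobiology import reference_registry, response


@dataclass(frozen=True)
class UtilityCurve:
    """U(D) on a dose grid with its argmax (ties broken toward lower dose)."""

    dose_grid: np.ndarray
    utility: np.ndarray
    optimal_dose: float
    rflc_at_optimum: float


#: Default utility search grid: 0.5 Gy steps over the range of clinical interest.
DEFAULT_UTILITY_GRID = np.arange(70.0, 100.0 + 1e-9, 0.5)


def utility_curve(tcp, ntcp, grid) -> UtilityCurve:
    """Pointwise ``TCP * (1 - NTCP)`` with deterministic argmax.

    Ties at the maximum are broken toward the lowest dose (least
    irradiation for the same risk-free control).
    """
    tcp = np.asarray(tcp, dtype=float)
    ntcp = np.asarray(ntcp, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not (tcp.size == ntcp.size == grid.size):
        raise GridError("tcp, ntcp and grid must have equal lengths")
    if np.any((tcp < 0) | (tcp > 1) | (ntcp < 0) | (ntcp > 1)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    u = tcp * (1.0 - ntcp)
    k = int(np.argmax(u))  # argmax returns the first (lowest-dose) maximizer
    return UtilityCurve(dose_grid=grid, utility=u,
                        optimal_dose=float(grid[k]), rflc_at_optimum=float(u[k]))


def reference_utility(tcp_name: str, *, registry=None,
                      ntcp_name: str = "NTCP_ref",
                      grid=None) -> UtilityCurve:
    """Utility of a reference TCP curve against the reference NTCP curve."""
    if registry is None:
        registry = reference_registry()
    if tcp_name not in registry:
        raise InvalidInputError(f"unknown curve {tcp_name!r}")
    if grid is None:
        grid = DEFAULT_UTILITY_GRID
    grid = np.asarray(grid, dtype=float)
    tcp = response(grid, registry[tcp_name])
    ntcp = response(grid, registry[ntcp_name])
    return utility_curve(tcp, ntcp, grid)


def convolved_utility(tcp_rprime, oar_rprime, grid) -> UtilityCurve:
    """Utility of a convolved TCP curve against the combined convolved
    organ-at-risk complication curve on a shared grid."""
    return utility_curve(np.asarray(tcp_rprime, dtype=float),
                         np.asarray(oar_rprime, dtype=float), grid)
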