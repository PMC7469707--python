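"""Global sensitivity of peak contact pressure to (h_T, E_lig).

The response at each point of a uniform rectilinear grid over the spring
length threshold h_T and the ligament Young's modulus E_lig is the maximum
over the whole stance of the per-frame peak contact pressure, recomputed
by a full extended-DEM stance run with the overridden parameters.  Grid
points are independent, so results do not depend on evaluation order.
Sensitivities are finite-difference gradients of the response surface
(central differences in the interior, one-sided at the edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ligaments import LigamentBundle, with_modulus
from .mattress import MaterialParams
from .solver import SolverParams
from .stance import LoadFrame, run_stance
from .surfaces import JointAxis, TriSurface

logger = logging.getLogger("ankledem.sensitivity")


@dataclass
class SensitivityGrid:
    """Response surface of max-over-stance peak pressure (MPa)."""

    hT_values: np.ndarray     # mm
    Elig_values: np.ndarray   # MPa
    response: np.ndarray      # (n_hT, n_Elig), NaN where a run failed
    errors: dict = field(default_factory=dict)  # (i, j) -> reason
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (hT, Elig, response) table."""
        H, E = np.meshgrid(self.hT_values, self.Elig_values, indexing="ij")
        return pd.DataFrame({
            "hT_mm": H.ravel(),
            "Elig_MPa": E.ravel(),
            "max_peak_pressure_MPa": self.response.ravel(),
        })


def evaluate_point(
    geometry, bundles, frames, material, solver_params, hT, Elig,
    method: str = "edem",
) -> float:
    """Max-over-stance peak pressure for one (h_T, E_lig) override."""
    talus, tibia, axis = geometry
    mat = replace(material, h_threshold=float(hT), E_ligament=float(Elig))
    bnd = with_modulus(bundles, float(Elig)) if bundles else bundles
    result = run_stance(talus, tibia, axis, bnd, frames, mat, solver_params,
                        method=method)
    return float(np.nanmax(result.peak_pressure))


def run_sensitivity_grid(
    geometry: tuple[TriSurface, TriSurface, JointAxis],
    bundles: list[LigamentBundle] | None,
    frames: list[LoadFrame],
    material: MaterialParams | None = None,
    solver_params: SolverParams | None = None,
    hT_range=(2.5, 4.5),
    Elig_range=(200.0, 350.0),
    grid=(20, 20),
    method: str = "edem",
) -> SensitivityGrid:
    """Sweep a uniform (h_T, E_lig) grid, re-running the stance per point.

    A failing stance run is recorded as NaN with its reason; it does not
    abort the sweep.  Collapsed ranges (min == max) are allowed and yield
    a constant axis.
    """
    material = material or MaterialParams()
    solver_params = solver_params or SolverParams()
    n_h, n_e = grid
    if n_h < 1 or n_e < 1:
        raise ValueError("grid must be at least 1x1 per axis")
    hT_values = np.linspace(hT_range[0], hT_range[1], n_h)
    Elig_values = np.linspace(Elig_range[0], Elig_range[1], n_e)
    response = np.full((n_h, n_e), np.nan)
    errors: dict = {}
    for i, hT in enumerate(hT_values):
        for j, El in enumerate(Elig_values):
            try:
                response[i, j] = evaluate_point(
                    geometry, bundles, frames, material, solver_params,
                    hT, El, method=method)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                errors[(i, j)] = str(exc)
                logger.warning("grid point (hT=%.3g, Elig=%.3g) failed: %s",
                               hT, El, exc)
    return SensitivityGrid(
        hT_values=hT_values, Elig_values=Elig_values,
        response=response, errors=errors,
        metadata={"method": method, "material": material},
    )


def gradient_map(grid: SensitivityGrid):
    """Finite-difference gradient of the response surface.

    Returns ``(d_dhT, d_dElig)``, each shaped like the response (MPa/mm
    and MPa/MPa).  An axis with fewer than two points, or stencils
    touching a failed (NaN) point, yield NaN (masked) entries.
    """
    resp = grid.response
    n_h, n_e = resp.shape
    d_h = np.full_like(resp, np.nan)
    d_e = np.full_like(resp, np.nan)
    if n_h >= 2:
        d_h = np.gradient(resp, grid.hT_values, axis=0)
    if n_e >= 2:
        d_e = np.gradient(resp, grid.Elig_values, axis=1)
    # a failed point has no gradient of its own (NaN already spreads to the
    # neighbouring central-difference stencils)
    failed = np.isnan(resp)
    d_h[failed] = np.nan
    d_e[failed] = np.nan
    return d_h, d_e
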