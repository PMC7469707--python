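"""Drive the contact solver through a stance-phase time series.

Per frame: the tibia (and the ligaments' fixed-side endpoints) is re-posed
from the reference configuration to the frame's dorsiflexion angle about
the joint axis; springs are recast from the current talus pose,
thresholded, and given their gap-dependent stiffnesses; the joint contact
force is applied as a point load (translation-only equilibrium, so only
the force vector matters); the equilibrium is solved.  In the extended
method the talus is then moved by the computed increment and the spring
push-back state is carried to the next frame; in the classical method the
talus never leaves the reference pose and no state is kept.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ligaments import LigamentBundle
from .mattress import MaterialParams, SpringMattress, build_mattress
from .solver import (ContactSolution, SolverError, SolverParams, SolverState,
                     advance_state, pressure_map, solve_equilibrium_dem,
                     solve_equilibrium_edem)
from .surfaces import (JointAxis, TriSurface, rotate_about_axis,
                       rotate_points_about_axis, translate_surface)

logger = logging.getLogger("ankledem.stance")


class GaitCSVError(ValueError):
    """Malformed gait table."""


class StanceError(RuntimeError):
    """A frame of the stance simulation failed."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from clinical force columns to the anatomical frame.

    The anatomical frame is +x anterior, +y superior, +z lateral (right
    side).  Gait tables report signed medial/lateral, posterior/anterior
    and superior/inferior components; the sign conventions below (positive
    column value = first-named direction) are configurable because they
    are a reporting convention, not an anatomical fact.
    """

    ml_sign: float = -1.0  # +ML (medial) maps to -z (medial = -lateral)
    pa_sign: float = -1.0  # +PA (posterior) maps to -x (posterior = -anterior)
    si_sign: float = +1.0  # +SI (superior) maps to +y

    def to_anatomical(self, ml: float, pa: float, si: float) -> np.ndarray:
        return np.array([self.pa_sign * pa, self.si_sign * si,
                         self.ml_sign * ml])

    def from_anatomical(self, force) -> tuple[float, float, float]:
        fx, fy, fz = np.asarray(force, dtype=float)
        return fz / self.ml_sign, fx / self.pa_sign, fy / self.si_sign


@dataclass(frozen=True)
class LoadFrame:
    """One stance time point: time (s or percent), dorsiflexion angle
    (deg, positive = dorsiflexion) and joint contact force (N, anatomical
    frame) applied to the talus."""

    time: float
    angle_deg: float
    force: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "force",
                           np.asarray(self.force, dtype=float).reshape(3))


_REQUIRED_COLS = ("angle_deg", "force_ml_N", "force_pa_N", "force_si_N")


def load_gait_csv(path, column_map: ColumnMap | None = None) -> list[LoadFrame]:
    """Parse a gait table CSV into load frames.

    Expected columns: a time column (``percent_stance`` or ``time_s``) plus
    ``angle_deg, force_ml_N, force_pa_N, force_si_N`` (signed clinical
    components, mapped to the anatomical frame by ``column_map``).  Time
    must be strictly increasing.
    """
    column_map = column_map or ColumnMap()
    df = pd.read_csv(path)
    time_col = next((c for c in ("percent_stance", "time_s") if c in df), None)
    if time_col is None:
        raise GaitCSVError("missing time column (percent_stance or time_s)")
    missing = [c for c in _REQUIRED_COLS if c not in df]
    if missing:
        raise GaitCSVError(f"missing column(s): {missing}")
    t = df[time_col].to_numpy(dtype=float)
    if not (np.diff(t) > 0).all():
        raise GaitCSVError("time column must be strictly increasing")
    return [
        LoadFrame(
            time=float(row[time_col]),
            angle_deg=float(row["angle_deg"]),
            force=column_map.to_anatomical(
                float(row["force_ml_N"]), float(row["force_pa_N"]),
                float(row["force_si_N"]),
            ),
        )
        for _, row in df.iterrows()
    ]


def write_gait_csv(frames: list[LoadFrame], path,
                   column_map: ColumnMap | None = None) -> None:
    column_map = column_map or ColumnMap()
    rows = []
    for fr in frames:
        ml, pa, si = column_map.from_anatomical(fr.force)
        rows.append((fr.time, fr.angle_deg, ml, pa, si))
    pd.DataFrame(rows, columns=["time_s", *_REQUIRED_COLS]).to_csv(
        path, index=False)


@dataclass
class StanceResult:
    """Per-frame contact solutions plus summary curves."""

    method: str                       # 'edem' or 'dem'
    frames: list[LoadFrame]
    solutions: list[ContactSolution | None]
    peak_pressure: np.ndarray         # MPa per frame
    active_area: np.ndarray           # cm^2 per frame
    u_cum: np.ndarray                 # (n, 3) mm cumulative talus translation
    mattresses: list[SpringMattress] = field(repr=False, default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time": [f.time for f in self.frames],
                "angle_deg": [f.angle_deg for f in self.frames],
                "peak_MPa": self.peak_pressure,
                "area_cm2": self.active_area,
                "ux_mm": self.u_cum[:, 0],
                "uy_mm": self.u_cum[:, 1],
                "uz_mm": self.u_cum[:, 2],
            }
        )


def _surface_hash(surface: TriSurface) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(surface.vertices).tobytes())
    h.update(np.ascontiguousarray(surface.faces).tobytes())
    return h.hexdigest()[:16]


def _pose_bundles(bundles, axis, angle_deg, rotate_fixed):
    if not bundles or not rotate_fixed or angle_deg == 0.0:
        return bundles
    return [
        b.with_fixed_points(
            rotate_points_about_axis(b.fixed_points, axis, angle_deg))
        for b in bundles
    ]


def run_stance(
    talus: TriSurface,
    tibia: TriSurface,
    axis: JointAxis,
    bundles: list[LigamentBundle] | None,
    frames: list[LoadFrame],
    material: MaterialParams | None = None,
    solver_params: SolverParams | None = None,
    method: str = "edem",
    rotate_ligament_fixed_points: bool = True,
    skip_failed_frames: bool = False,
    keep_mattresses: bool = False,
) -> StanceResult:
    """Simulate a full stance phase with the chosen contact method.

    The tibia is re-posed from the reference pose each frame (absolute
    frame angle, no incremental drift).  A failing frame aborts the run
    with the frame index attached, unless ``skip_failed_frames`` logs it
    and records NaN summaries instead.
    """
    if method not in ("edem", "dem"):
        raise ValueError("method must be 'edem' or 'dem'")
    if not frames:
        raise ValueError("frames must be non-empty")
    material = material or MaterialParams()
    solver_params = solver_params or SolverParams()

    state = SolverState.zero(talus.n_faces)
    solutions: list[ContactSolution | None] = []
    peaks, areas, u_hist, mats = [], [], [], []
    for idx, frame in enumerate(frames):
        tib = rotate_about_axis(tibia, axis, frame.angle_deg)
        bnd = _pose_bundles(bundles, axis, frame.angle_deg,
                            rotate_ligament_fixed_points)
        tal = (translate_surface(talus, state.u_cum)
               if method == "edem" else talus)
        try:
            mattress = build_mattress(tal, tib, material)
            # stored forces live per talar triangle and survive the recast
            if method == "edem":
                sol, state = solve_equilibrium_edem(
                    mattress, bnd, frame.force, state, solver_params)
                state = advance_state(state, sol, mattress)
            else:
                sol = solve_equilibrium_dem(
                    mattress, bnd, frame.force, solver_params)
        except SolverError as exc:
            if skip_failed_frames:
                logger.warning("frame %d (t=%s) failed: %s", idx, frame.time, exc)
                solutions.append(None)
                peaks.append(np.nan)
                areas.append(np.nan)
                u_hist.append(state.u_cum.copy())
                if keep_mattresses:
                    mats.append(None)
                continue
            raise StanceError(f"frame {idx} (t={frame.time}) failed: {exc}") from exc
        _, peak, area = pressure_map(sol, mattress)
        solutions.append(sol)
        peaks.append(peak)
        areas.append(area)
        u_hist.append(state.u_cum.copy() if method == "edem" else np.zeros(3))
        if keep_mattresses:
            mats.append(mattress)

    return StanceResult(
        method=method,
        frames=list(frames),
        solutions=solutions,
        peak_pressure=np.asarray(peaks),
        active_area=np.asarray(areas),
        u_cum=np.asarray(u_hist),
        mattresses=mats,
        metadata={
            "material": material,
            "solver_params": solver_params,
            "talus_hash": _surface_hash(talus),
            "tibia_hash": _surface_hash(tibia),
        },
    )


def compare_methods(edem: StanceResult, dem: StanceResult) -> pd.DataFrame:
    """Per-frame EDEM-vs-DEM deltas of active area, peak pressure, and
    active-set overlap (shared active triangles / union; 1.0 when both
    empty).  Stance averages are attached as ``DataFrame.attrs``."""
    if edem.n_frames != dem.n_frames:
        raise ValueError("results have mismatched frame counts")
    rows = []
    for i in range(edem.n_frames):
        se, sd = edem.solutions[i], dem.solutions[i]
        if se is None or sd is None:
            rows.append((i, np.nan, np.nan, np.nan))
            continue
        a, b = set(se.active_ids.tolist()), set(sd.active_ids.tolist())
        union = a | b
        overlap = (len(a & b) / len(union)) if union else 1.0
        rows.append((
            i,
            edem.active_area[i] - dem.active_area[i],
            edem.peak_pressure[i] - dem.peak_pressure[i],
            overlap,
        ))
    df = pd.DataFrame(rows, columns=["frame", "delta_area_cm2",
                                     "delta_peak_MPa", "overlap"])
    df.attrs["mean_area_edem_cm2"] = float(np.nanmean(edem.active_area))
    df.attrs["mean_area_dem_cm2"] = float(np.nanmean(dem.active_area))
    df.attrs["mean_delta_area_cm2"] = float(np.nanmean(df.delta_area_cm2))
    df.attrs["mean_delta_peak_MPa"] = float(np.nanmean(df.delta_peak_MPa))
    return df
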