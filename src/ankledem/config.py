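"""Validated run configuration (YAML) and result serialization.

The schema bakes in the homogeneous material defaults (cartilage
E = 10.35 MPa, nu = 0.4247, spring length threshold h_T = 3.5 mm, ligament
E = 255 MPa); every field can be overridden.  Unknown keys are rejected so
typos fail loudly before any computation.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Strict):
    E_cartilage: float = Field(10.35, gt=0, description="MPa")
    nu: float = Field(0.4247, ge=0, lt=0.5)
    h_threshold: float = Field(3.5, gt=0, description="mm")
    E_ligament: float = Field(255.0, gt=0, description="MPa")


class LigamentConfig(_Strict):
    enabled: bool = True
    fibre_area: float = Field(1.0, gt=0, description="mm^2 per fibre")
    fibres_per_bundle: int = Field(5, ge=1)
    tension_only: bool = True
    rotate_fixed_with_tibia: bool = True


class SolverConfig(_Strict):
    residual_tol: Optional[float] = Field(None, gt=0)
    max_active_set_iterations: Optional[int] = Field(None, ge=1)
    stiffness_update: Literal["lagged", "within_step"] = "lagged"
    removal_rule: Literal["all_tensile", "most_tensile_only"] = "all_tensile"


class FixtureConfig(_Strict):
    kind: Literal["flat_congruent", "cylinder_congruent",
                  "cylinder_incongruent", "flat_with_depressions"] = (
        "cylinder_congruent")
    extent: float = Field(20.0, gt=0)
    radius_talus: float = Field(20.0, gt=0)
    radius_tibia: Optional[float] = Field(None, gt=0)
    arc_deg: float = Field(90.0, gt=0)
    width: float = Field(20.0, gt=0)
    gap: float = Field(2.0, gt=0)
    resolution: int = Field(800, ge=8)


class GeometryConfig(_Strict):
    talus_path: str
    tibia_path: str
    units_scale: float = Field(1.0, gt=0)


class ProfileConfig(_Strict):
    shape: Literal["half_sine", "table1_like"] = "half_sine"
    n_frames: int = Field(21, ge=3)
    peak_force: float = Field(2000.0, ge=0, description="N")
    peak_angle: float = Field(15.0, description="deg dorsiflexion")


class RunConfig(_Strict):
    fixture: Optional[FixtureConfig] = None
    geometry: Optional[GeometryConfig] = None
    gait_csv: Optional[str] = None
    profile: Optional[ProfileConfig] = None
    material: MaterialConfig = MaterialConfig()
    solver: SolverConfig = SolverConfig()
    ligaments: LigamentConfig = LigamentConfig()
    method: Literal["edem", "dem", "both"] = "edem"
    outdir: str = "ankledem_out"
    log_level: str = "INFO"
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.fixture is None) == (self.geometry is None):
            raise ValueError("specify exactly one of 'fixture' or 'geometry'")
        if (self.gait_csv is None) == (self.profile is None):
            raise ValueError("specify exactly one of 'gait_csv' or 'profile'")
        return self


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig.model_validate(data)


def _atomic_write(path: str, data: str) -> None:
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", text=True)
    try:
        with os.fdopen(fd, "w", newline="") as f:
            f.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_results(result, outdir) -> list[str]:
    """Write a stance result: summary CSV, per-frame pressure CSVs and a
    reproducibility manifest.  Deterministic names and content; re-running
    overwrites atomically."""
    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    written = []
    summary_path = os.path.join(outdir, f"summary_{result.method}.csv")
    _atomic_write(summary_path, result.summary().to_csv(index=False))
    written.append(summary_path)
    pdir = os.path.join(outdir, f"pressures_{result.method}")
    os.makedirs(pdir, exist_ok=True)
    for i, sol in enumerate(result.solutions):
        fpath = os.path.join(pdir, f"frame_{i:03d}.csv")
        if sol is None:
            _atomic_write(fpath, "triangle_id,pressure_MPa\n")
        else:
            lines = ["triangle_id,pressure_MPa"]
            lines += [f"{int(t)},{p!r}" for t, p in
                      zip(sol.active_ids, sol.pressures)]
            _atomic_write(fpath, "\n".join(lines) + "\n")
        written.append(fpath)
    manifest = {
        "package_version": __version__,
        "method": result.method,
        "n_frames": result.n_frames,
        "talus_hash": result.metadata.get("talus_hash"),
        "tibia_hash": result.metadata.get("tibia_hash"),
    }
    mpath = os.path.join(outdir, f"manifest_{result.method}.json")
    _atomic_write(mpath, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def export_pressure_ply(result, mattress_surface, frame: int, path) -> None:
    """Write the talar surface coloured by the frame's pressure field (PLY)."""
    import trimesh

    sol = result.solutions[frame]
    pressures = np.zeros(mattress_surface.n_faces)
    if sol is not None:
        pressures[sol.active_ids] = sol.pressures
    peak = pressures.max() or 1.0
    shade = (255 * pressures / peak).astype(np.uint8)
    colors = np.column_stack([
        shade, np.zeros_like(shade), 255 - shade,
        np.full_like(shade, 255),
    ])
    mesh = trimesh.Trimesh(vertices=mattress_surface.vertices,
                           faces=mattress_surface.faces, process=False)
    mesh.visual.face_colors = colors
    mesh.export(path)
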