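"""The bed of contact springs spanning the articular gap.

Each talar triangle carries at most one spring: a ray from the triangle
centroid along the triangle normal, ending where it first meets the tibial
surface.  The ray length is the local cartilage gap h_i; springs longer
than the threshold h_T (default 3.5 mm, twice a typical undeformed
tibiotalar cartilage layer) are excluded from the nominal contact region.
The spring stiffness follows the elastic-foundation (Winkler) estimate

    k_i = s(nu) * E * A_i / h_i,      s(nu) = (1 - nu) / ((1 - 2 nu)(1 + nu))

so a thinner local gap means a stiffer spring (strain-dependent stiffness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .surfaces import TriSurface

logger = logging.getLogger("ankledem.mattress")

#: gaps below this (mm) make the Winkler stiffness diverge; treated as
#: interpenetration and raised as an error rather than clamped
LENGTH_FLOOR = 1e-3

#: rays closer than this to parallel with a triangle plane are treated as misses
_PARALLEL_EPS = 1e-12
#: tolerance on barycentric coordinates so rays through shared edges still hit
_BARY_EPS = 1e-9
#: minimum positive ray parameter for a valid hit
_T_MIN = 1e-12


class SpringStatus(IntEnum):
    ABSENT = 0          # normal ray never meets the tibia
    OVER_THRESHOLD = 1  # gap above h_T: outside the nominal contact region
    NOMINAL = 2         # candidate for contact at this time point
    ACTIVE = 3          # in compression at equilibrium
    RELEASED = 4        # removed during the tension-release iteration


class CastError(RuntimeError):
    """No spring intersects the tibia (disjoint or mis-oriented surfaces)."""


class InterpenetrationError(RuntimeError):
    """A spring gap fell below the length floor (surfaces interpenetrate)."""


@dataclass(frozen=True)
class MaterialParams:
    """Homogeneous material and threshold parameters.

    E_cartilage : MPa, cartilage Young's modulus (default 10.35)
    nu : cartilage Poisson ratio (default 0.4247)
    h_threshold : mm, spring-length threshold h_T (default 3.5)
    E_ligament : MPa, ligament Young's modulus (default 255)
    """

    E_cartilage: float = 10.35
    nu: float = 0.4247
    h_threshold: float = 3.5
    E_ligament: float = 255.0

    def __post_init__(self):
        if self.E_cartilage <= 0:
            raise ValueError("E_cartilage must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must satisfy 0 <= nu < 0.5")
        if self.h_threshold <= 0:
            raise ValueError("h_threshold must be positive")
        if self.E_ligament <= 0:
            raise ValueError("E_ligament must be positive")


def poisson_factor(nu: float) -> float:
    """Confined-compression factor s(nu) = (1 - nu)/((1 - 2 nu)(1 + nu)).

    Diverges at the incompressible limit nu -> 0.5, which is rejected.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    if nu >= 0.5:
        raise ValueError("nu must be below the incompressible limit 0.5")
    return (1.0 - nu) / ((1.0 - 2.0 * nu) * (1.0 + nu))


@dataclass(frozen=True)
class Spring:
    """Read-only view of one contact spring (one talar triangle)."""

    triangle_id: int
    origin: np.ndarray      # mm, talar centroid
    direction: np.ndarray   # unit, talar normal (points toward the tibia)
    length: float           # mm, current gap h_i (nan if absent)
    area: float             # mm^2, talar triangle area A_i
    stiffness: float        # N/mm
    stored_force: float     # N, push-back force carried from the previous step
    status: SpringStatus


@dataclass
class SpringMattress:
    """One spring slot per talar triangle (struct-of-arrays layout)."""

    origins: np.ndarray       # (m, 3)
    directions: np.ndarray    # (m, 3)
    lengths: np.ndarray       # (m,) nan where absent
    areas: np.ndarray         # (m,)
    stiffness: np.ndarray     # (m,) nan until computed
    stored_forces: np.ndarray  # (m,) >= 0
    status: np.ndarray        # (m,) SpringStatus values
    material: MaterialParams = field(default_factory=MaterialParams)

    @property
    def n_springs(self) -> int:
        return len(self.lengths)

    def spring(self, i: int) -> Spring:
        return Spring(
            triangle_id=i,
            origin=self.origins[i],
            direction=self.directions[i],
            length=float(self.lengths[i]),
            area=float(self.areas[i]),
            stiffness=float(self.stiffness[i]),
            stored_force=float(self.stored_forces[i]),
            status=SpringStatus(int(self.status[i])),
        )

    def mask(self, *statuses: SpringStatus) -> np.ndarray:
        return np.isin(self.status, [int(s) for s in statuses])

    def copy(self) -> "SpringMattress":
        return SpringMattress(
            origins=self.origins.copy(),
            directions=self.directions.copy(),
            lengths=self.lengths.copy(),
            areas=self.areas.copy(),
            stiffness=self.stiffness.copy(),
            stored_forces=self.stored_forces.copy(),
            status=self.status.copy(),
            material=self.material,
        )


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def _ray_mesh_min_t(origins: np.ndarray, directions: np.ndarray,
                    mesh: TriSurface, chunk: int = 128) -> np.ndarray:
    """Nearest positive ray parameter against every mesh triangle.

    Vectorised Moller-Trumbore, front and back faces alike; returns inf
    where a ray misses the mesh entirely.
    """
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    out = np.full(len(origins), np.inf)
    for start in range(0, len(origins), chunk):
        O = origins[start:start + chunk]        # (r, 3)
        D = directions[start:start + chunk]     # (r, 3)
        p = np.cross(D[:, None, :], e2[None, :, :])          # (r, m, 3)
        det = np.einsum("tj,rtj->rt", e1, p)                 # (r, m)
        ok = np.abs(det) > _PARALLEL_EPS
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = O[:, None, :] - v0[None, :, :]                # (r, m, 3)
        u = np.einsum("rtj,rtj->rt", tvec, p) * inv_det
        q = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rj,rtj->rt", D, q) * inv_det
        t = np.einsum("tj,rtj->rt", e2, q) * inv_det
        hit = (
            ok
            & (u >= -_BARY_EPS)
            & (v >= -_BARY_EPS)
            & (u + v <= 1.0 + _BARY_EPS)
            & (t > _T_MIN)
        )
        t = np.where(hit, t, np.inf)
        out[start:start + chunk] = t.min(axis=1)
    return out


def cast_springs(talus: TriSurface, tibia: TriSurface,
                 material: MaterialParams | None = None) -> SpringMattress:
    """Cast one normal ray per talar triangle onto the tibial surface.

    The spring length is the distance along the talar normal from the
    triangle centroid to the nearest tibial intersection; triangles whose
    ray misses the tibia get status ``ABSENT``.  All hit springs start
    ``NOMINAL`` with zero stored force.
    """
    material = material or MaterialParams()
    t = _ray_mesh_min_t(talus.centroids, talus.normals, tibia)
    hit = np.isfinite(t)
    if not hit.any():
        raise CastError(
            "no talar normal ray intersects the tibia "
            "(surfaces disjoint or mis-oriented)"
        )
    m = talus.n_faces
    lengths = np.where(hit, t, np.nan)
    status = np.where(hit, int(SpringStatus.NOMINAL), int(SpringStatus.ABSENT))
    return SpringMattress(
        origins=talus.centroids.copy(),
        directions=talus.normals.copy(),
        lengths=lengths,
        areas=talus.areas.copy(),
        stiffness=np.full(m, np.nan),
        stored_forces=np.zeros(m),
        status=status.astype(np.int8),
        material=material,
    )


def apply_length_threshold(mattress: SpringMattress) -> SpringMattress:
    """Split non-absent springs into nominal (h <= h_T) and over-threshold.

    A length exactly equal to the threshold is kept (only strictly longer
    springs are removed).  Idempotent; an empty nominal region is legal but
    logged as a warning.
    """
    out = mattress.copy()
    present = out.status != int(SpringStatus.ABSENT)
    over = present & (out.lengths > out.material.h_threshold)
    out.status[present] = int(SpringStatus.NOMINAL)
    out.status[over] = int(SpringStatus.OVER_THRESHOLD)
    if present.any() and not (present & ~over).any():
        logger.warning("length threshold %.3g mm leaves an empty nominal region",
                       out.material.h_threshold)
    return out


def compute_stiffnesses(mattress: SpringMattress) -> SpringMattress:
    """Assign k_i = s(nu) * E * A_i / h_i to every non-absent spring."""
    out = mattress.copy()
    present = out.status != int(SpringStatus.ABSENT)
    too_short = present & (out.lengths <= LENGTH_FLOOR)
    if too_short.any():
        ids = np.flatnonzero(too_short)[:10].tolist()
        raise InterpenetrationError(
            f"spring gap at triangle(s) {ids} is below the length floor "
            f"{LENGTH_FLOOR} mm; surfaces interpenetrate"
        )
    s = poisson_factor(out.material.nu)
    k = s * out.material.E_cartilage * out.areas / out.lengths
    out.stiffness = np.where(present, k, np.nan)
    return out


def build_mattress(talus: TriSurface, tibia: TriSurface,
                   material: MaterialParams | None = None) -> SpringMattress:
    """cast -> threshold -> stiffness in one call (one stance frame's setup)."""
    m = cast_springs(talus, tibia, material)
    m = apply_length_threshold(m)
    return compute_stiffnesses(m)


def export_gap_csv(mattress: SpringMattress, path) -> None:
    """Write the per-triangle gap map (triangle_id, length, area, status)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "triangle_id": np.arange(mattress.n_springs),
            "length_mm": mattress.lengths,
            "area_mm2": mattress.areas,
            "status": [SpringStatus(int(s)).name.lower() for s in mattress.status],
        }
    )
    df.to_csv(path, index=False)
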