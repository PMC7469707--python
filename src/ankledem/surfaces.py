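"""Triangulated articular surfaces, rigid transforms, and joint-axis fitting.

The contact model treats the talus and the distal tibia as rigid,
triangulated articular surfaces.  Everything downstream (spring casting,
equilibrium, the stance pipeline) consumes per-triangle centroids, unit
normals and areas, so those are computed once per surface and carried with
it.  The physiological hinge axis of the tibiotalar joint is recovered as
the axis of the least-squares cylinder fitted to the talar articular
surface, which is how the single dorsiflexion/plantarflexion degree of
freedom is defined.

Units are mm throughout; angles are degrees at every public boundary and
radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

logger = logging.getLogger("ankledem.surfaces")

#: triangles with area below this (mm^2) are considered degenerate
DEGENERATE_AREA = 1e-12

_SUPPORTED_FORMATS = {".stl", ".obj", ".ply"}


class SurfaceError(ValueError):
    """Invalid or degenerate surface input."""


class CylinderFitError(RuntimeError):
    """The least-squares cylinder fit failed or the input is degenerate."""


def _triangle_data(vertices: np.ndarray, faces: np.ndarray):
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    centroids = (v0 + v1 + v2) / 3.0
    cross = np.cross(v1 - v0, v2 - v0)
    cross_norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * cross_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / cross_norm[:, None]
    return centroids, normals, areas


@dataclass(frozen=True)
class TriSurface:
    """A rigid triangulated articular surface.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    centroids, normals, areas : per-triangle derived data (mm, unit, mm^2)
    """

    vertices: np.ndarray
    faces: np.ndarray
    centroids: np.ndarray = None  # type: ignore[assignment]
    normals: np.ndarray = None  # type: ignore[assignment]
    areas: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        vertices = np.ascontiguousarray(self.vertices, dtype=float)
        faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise SurfaceError("vertices must be an (n, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise SurfaceError("faces must be an (m, 3) array")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise SurfaceError("face indices out of range")
        if faces.size and (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        ).any():
            raise SurfaceError("faces must reference three distinct vertices")
        centroids, normals, areas = _triangle_data(vertices, faces)
        if (areas <= DEGENERATE_AREA).any():
            bad = np.flatnonzero(areas <= DEGENERATE_AREA)
            raise SurfaceError(f"degenerate (zero-area) faces: {bad[:10].tolist()}")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "normals", normals)
        object.__setattr__(self, "areas", areas)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def flipped(self) -> "TriSurface":
        """Reverse the winding (and hence the normals) of every face."""
        return TriSurface(self.vertices.copy(), self.faces[:, ::-1].copy())


def has_consistent_orientation(surface: TriSurface) -> bool:
    """True if every shared edge is traversed in opposite order by its two faces."""
    seen: set[tuple[int, int]] = set()
    for a, b, c in surface.faces:
        for e in ((int(a), int(b)), (int(b), int(c)), (int(c), int(a))):
            if e in seen:
                return False
            seen.add(e)
    return True


@dataclass(frozen=True)
class JointAxis:
    """A line in space: the hinge (dorsiflexion/plantarflexion) axis."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        point = np.asarray(self.point, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "direction", direction / norm)


@dataclass(frozen=True)
class RigidPose:
    """A proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_surface(self, surface: TriSurface) -> TriSurface:
        return TriSurface(self.apply(surface.vertices), surface.faces.copy())


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def load_surface(path, units_scale: float = 1.0) -> TriSurface:
    """Load an STL/OBJ/PLY mesh as a :class:`TriSurface`.

    Degenerate (zero-area) faces are removed with a logged warning; vertex
    coordinates are multiplied by ``units_scale`` (e.g. 1000 for a mesh
    stored in metres).
    """
    import os

    if units_scale <= 0:
        raise ValueError("units_scale must be positive")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_FORMATS:
        raise SurfaceError(f"unsupported mesh format {ext!r} (need STL/OBJ/PLY)")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mesh = trimesh.load(path, file_type=ext.lstrip("."), force="mesh", process=False)
    vertices = np.asarray(mesh.vertices, dtype=float) * units_scale
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if faces.size == 0:
        raise SurfaceError(f"{path}: mesh contains no faces")
    _, _, areas = _triangle_data(vertices, faces)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    keep = (areas > DEGENERATE_AREA) & distinct
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: removed %d degenerate face(s)", path, n_dropped)
        faces = faces[keep]
    if faces.size == 0:
        raise SurfaceError(f"{path}: empty mesh after degenerate-face removal")
    return TriSurface(vertices, faces)


def save_surface(surface: TriSurface, path) -> None:
    """Write a surface to STL/OBJ/PLY (format chosen from the extension)."""
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    mesh.export(path)


def triangle_properties(surface: TriSurface):
    """Return ``(centroids, normals, areas)`` for every face.

    Centroid = mean of the three vertices; normal = unit cross product of
    the edges following the face winding; area = half the cross-product
    magnitude.
    """
    return surface.centroids, surface.normals, surface.areas


# ---------------------------------------------------------------------------
# joint axis: least-squares cylinder fit
# ---------------------------------------------------------------------------


def _direction_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _plane_basis(d: np.ndarray):
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _kasa_circle(x: np.ndarray, y: np.ndarray):
    # algebraic circle fit: solves 2ax + 2by + c = x^2 + y^2 in least squares
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CylinderFitError("projected points are collinear")
    a, b0, c = sol
    r2 = c + a * a + b0 * b0
    return a, b0, np.sqrt(max(r2, 0.0))


def _cylinder_residuals(angles, pts):
    d = _direction_from_angles(*angles)
    e1, e2 = _plane_basis(d)
    x = pts @ e1
    y = pts @ e2
    a, b, r = _kasa_circle(x, y)
    return np.hypot(x - a, y - b) - r


def fit_cylinder_axis(
    surface: TriSurface, reference_direction=(0.0, 0.0, 1.0)
) -> JointAxis:
    """Fit a least-squares cylinder to the triangle centroids and return its axis.

    The axis direction is optimised by Gauss-Newton (scipy ``least_squares``)
    over its two spherical angles; for each candidate direction the circle
    centre and radius in the orthogonal plane are recovered by a linear
    (Kasa) fit.  Initial directions are the three principal axes of the
    centroid covariance; the best converged fit wins.  The returned
    direction has positive dot product with ``reference_direction``
    (lateral, +z by default).
    """
    pts = surface.centroids
    if len(pts) < 20:
        raise CylinderFitError("need at least 20 triangles for a cylinder fit")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] / evals[-1] < 1e-10:
        raise CylinderFitError("surface is degenerate (coplanar or collinear points)")

    best = None
    for k in range(3):
        d0 = evecs[:, k]
        theta0 = np.arccos(np.clip(d0[2], -1.0, 1.0))
        phi0 = np.arctan2(d0[1], d0[0])
        try:
            res = least_squares(
                _cylinder_residuals, x0=[theta0, phi0], args=(pts,), method="lm"
            )
        except CylinderFitError:
            continue
        if res.status <= 0:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise CylinderFitError("cylinder fit did not converge")

    d = _direction_from_angles(*best.x)
    e1, e2 = _plane_basis(d)
    a, b, r = _kasa_circle(pts @ e1, pts @ e2)
    extent = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    if r > 100.0 * max(extent, 1.0):
        raise CylinderFitError("degenerate fit: radius far exceeds data extent "
                              "(points are nearly planar)")
    point = a * e1 + b * e2 + float(pts.mean(axis=0) @ d) * d
    rms = float(np.sqrt(np.mean(best.fun**2)))
    logger.info("cylinder fit: r=%.3f mm, residual RMS=%.2e mm", r, rms)
    ref = np.asarray(reference_direction, dtype=float)
    if float(d @ ref) < 0:
        d = -d
    return JointAxis(point=point, direction=d)


# ---------------------------------------------------------------------------
# rigid motions
# ---------------------------------------------------------------------------


def rotation_about_axis(axis: JointAxis, angle_deg: float) -> RigidPose:
    """Rigid pose rotating about the axis *line* by ``angle_deg``.

    Positive angles follow the right-hand rule about the axis direction;
    with the lateral (+z) ankle axis this is dorsiflexion.
    """
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis.direction).as_matrix()
    t = axis.point - R @ axis.point
    return RigidPose(rotation=R, translation=t)


def rotate_points_about_axis(points, axis: JointAxis, angle_deg: float) -> np.ndarray:
    return rotation_about_axis(axis, angle_deg).apply(points)


def rotate_about_axis(surface: TriSurface, axis: JointAxis, angle_deg: float) -> TriSurface:
    """Rodrigues rotation of the whole surface about the axis line."""
    return rotation_about_axis(axis, angle_deg).apply_surface(surface)


def translate_surface(surface: TriSurface, u) -> TriSurface:
    """Shift all vertices by ``u`` (mm); normals and areas are unchanged."""
    u = np.asarray(u, dtype=float).reshape(3)
    return TriSurface(surface.vertices + u, surface.faces.copy())


def orient_towards(talus: TriSurface, tibia: TriSurface, n_samples: int = 50,
                   seed: int = 0) -> TriSurface:
    """Ensure talar articular normals point toward the tibia.

    Casts rays from ``n_samples`` random triangles; if fewer than half hit
    the tibia the surface winding is flipped.
    """
    from .mattress import _ray_mesh_min_t  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    idx = rng.choice(talus.n_faces, size=min(n_samples, talus.n_faces), replace=False)
    t = _ray_mesh_min_t(talus.centroids[idx], talus.normals[idx], tibia)
    frac = float(np.isfinite(t).mean())
    if frac < 0.5:
        logger.warning(
            "talar normals hit the tibia for only %.0f%% of sampled rays; "
            "flipping surface orientation", 100 * frac,
        )
        return talus.flipped()
    return talus
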