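"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

import ankledem as ad
from ankledem.mattress import SpringStatus


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------


def naive_ray_cast(origin, direction, vertices, faces, eps=1e-12):
    """Brute-force nearest positive ray-mesh distance.

    Plane intersection followed by a same-side barycentric test, one
    triangle at a time — a different algorithm from the package's
    Moller-Trumbore caster.
    """
    best = np.inf
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    for f in faces:
        a, b, c = vertices[f[0]], vertices[f[1]], vertices[f[2]]
        n = np.cross(b - a, c - a)
        denom = n @ d
        if abs(denom) < eps:
            continue
        t = (n @ (a - o)) / denom
        if t <= eps or t >= best:
            continue
        p = o + t * d
        # p inside the triangle iff the sub-triangle normals all align with n
        s1 = np.cross(b - a, p - a) @ n
        s2 = np.cross(c - b, p - b) @ n
        s3 = np.cross(a - c, p - c) @ n
        tol = -1e-9 * (n @ n)
        if s1 >= tol and s2 >= tol and s3 >= tol:
            best = t
    return best


def naive_removal_solver(normals, stiffness, stored, F, tol=1e-10,
                         max_iter=1000):
    """Independent re-implementation of the tension-release iteration.

    Solves sum_i [k_i (n_i.u) + f_prev_i] n_i = F on a shrinking active
    set, removing every spring with f <= 0 each pass.  No ligaments.
    Returns (active index array, forces on the active set, u).
    """
    normals = np.asarray(normals, float)
    stiffness = np.asarray(stiffness, float)
    stored = np.asarray(stored, float)
    F = np.asarray(F, float)
    active = np.arange(len(stiffness))
    for _ in range(max_iter):
        n = normals[active]
        k = stiffness[active]
        K = np.zeros((3, 3))
        for j in range(len(active)):
            K += k[j] * np.outer(n[j], n[j])
        rhs = F - n.T @ stored[active]
        u = np.linalg.lstsq(K, rhs, rcond=None)[0]
        if np.linalg.norm(K @ u - rhs) > tol * max(1.0, np.linalg.norm(F)):
            raise RuntimeError("naive solver: inconsistent system")
        f = k * (n @ u) + stored[active]
        bad = f <= 0.0
        if not bad.any():
            return active, f, u
        active = active[~bad]
        if len(active) == 0:
            if np.linalg.norm(F) <= tol:
                return active, np.zeros(0), u
            raise RuntimeError("naive solver: lift-off")
    raise RuntimeError("naive solver: iteration cap")


def mattress_from_arrays(normals, stiffness, areas=None, lengths=None):
    """Assemble a SpringMattress directly from spring arrays (unit tests)."""
    normals = np.asarray(normals, float)
    m = len(normals)
    areas = np.ones(m) if areas is None else np.asarray(areas, float)
    lengths = np.full(m, 2.0) if lengths is None else np.asarray(lengths, float)
    return ad.SpringMattress(
        origins=np.zeros((m, 3)),
        directions=normals,
        lengths=lengths,
        areas=areas,
        stiffness=np.asarray(stiffness, float),
        stored_forces=np.zeros(m),
        status=np.full(m, int(SpringStatus.NOMINAL), dtype=np.int8),
        material=ad.MaterialParams(),
    )


# ---------------------------------------------------------------------------
# geometry fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def flat_joint():
    """20x20 mm congruent plates, 2 mm gap, 800 triangles, 400 mm^2."""
    return ad.make_joint(ad.FixtureSpec(kind="flat_congruent", extent=20.0,
                                        gap=2.0, resolution=800))


@pytest.fixture(scope="session")
def cylinder_joint():
    return ad.make_joint(ad.FixtureSpec(kind="cylinder_congruent",
                                        radius_talus=20.0, gap=1.5,
                                        arc_deg=90.0, resolution=400))


@pytest.fixture(scope="session")
def incongruent_joint():
    return ad.make_joint(ad.FixtureSpec(kind="cylinder_incongruent",
                                        radius_talus=20.0, radius_tibia=26.0,
                                        gap=1.5, arc_deg=90.0, resolution=400))


@pytest.fixture(scope="session")
def depression_joint():
    return ad.make_joint(ad.FixtureSpec(kind="flat_with_depressions",
                                        extent=20.0, gap=2.5, resolution=800))


@pytest.fixture
def material():
    return ad.MaterialParams()
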