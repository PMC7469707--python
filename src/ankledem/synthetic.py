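"""Parametric joint fixtures and stance-like load profiles.

Subject-specific articular geometry is rarely shareable, so every stage of
the pipeline is exercised on generated joints with known analytic
properties:

``flat_congruent``
    two parallel rectangular plates with a uniform gap — the closed-form
    oracle (uniform pressure F/A, displacement F h / (s(nu) E A)).
``cylinder_congruent``
    concentric cylinder sectors (convex talar trochlea inside a concave
    tibial plafond) with a constant radial gap; the generating axis is the
    ground truth for the cylinder-axis fit.
``cylinder_incongruent``
    tibial radius exceeding talar radius + gap, so the gap grows away from
    the contact line and the active area spreads with load.
``flat_with_depressions``
    a flat joint whose tibial plate is locally deepened; the springs under
    the depressions exceed the length threshold and form persistently
    inactive regions, mimicking local plafond topography.

Default dimensions give a total articular area of a few cm^2 and mean
triangle areas of order 0.1 mm^2 at high resolution, matching the scale of
an adult tibiotalar joint.

Load profiles are either an idealised half-sine stance ramp or a
piecewise-linear interpolation of a packaged seven-row table of measured
stance-phase ankle angles and joint contact forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ligaments import BUNDLE_NAMES
from .surfaces import JointAxis, TriSurface

_DEF_DEPRESSIONS = (((-5.0, 0.0), 2.5, 2.7), ((5.0, 0.0), 2.5, 2.7))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated joint.

    kind : one of flat_congruent, cylinder_congruent, cylinder_incongruent,
        flat_with_depressions.
    extent : mm, plate edge length (flat kinds).
    radius_talus / radius_tibia : mm (cylinder kinds; tibial defaults to
        talar + gap for the congruent case).
    arc_deg : cylinder sector arc; width : mm along the cylinder axis.
    gap : mm, nominal articular gap (cartilage thickness analogue).
    resolution : target triangle count per surface.
    depressions : tuple of ((cx, cz), radius, extra_depth) for
        flat_with_depressions.
    seed : recorded for provenance; generation is deterministic.
    """

    kind: str = "flat_congruent"
    extent: float = 20.0
    radius_talus: float = 20.0
    radius_tibia: float | None = None
    arc_deg: float = 90.0
    width: float = 20.0
    gap: float = 2.0
    resolution: int = 800
    depressions: tuple = _DEF_DEPRESSIONS
    seed: int = 0

    def __post_init__(self):
        kinds = ("flat_congruent", "cylinder_congruent",
                 "cylinder_incongruent", "flat_with_depressions")
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        if self.resolution < 8:
            raise ValueError("resolution must be at least 8 triangles")
        for dim in (self.extent, self.radius_talus, self.arc_deg, self.width):
            if dim <= 0:
                raise ValueError("all dimensions must be positive")
        if self.kind == "cylinder_incongruent":
            r_tib = self.radius_tibia
            if r_tib is None or r_tib <= self.radius_talus + self.gap:
                raise ValueError(
                    "incongruent fixture needs radius_tibia > radius_talus + gap")


@dataclass(frozen=True)
class JointFixture:
    """A generated joint: surfaces, hinge axis, ligament attachments, and
    fixture-specific metadata (e.g. expected over-threshold face ids)."""

    talus: TriSurface
    tibia: TriSurface
    axis: JointAxis
    attachments: dict
    meta: dict = field(default_factory=dict)


def _grid_plate(extent: float, n: int, y: float, up: bool):
    xs = np.linspace(-extent / 2, extent / 2, n + 1)
    zs = np.linspace(-extent / 2, extent / 2, n + 1)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    vertices = np.column_stack([X.ravel(), np.full(X.size, float(y)), Z.ravel()])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = (i + 1) * (n + 1) + j
            # winding chosen so the normal is +y; reversed for the tibia
            faces.append((a, a + 1, b))
            faces.append((a + 1, b + 1, b))
    faces = np.asarray(faces, dtype=np.int64)
    if not up:
        faces = faces[:, ::-1]
    return vertices, faces


def _cylinder_sector(radius: float, arc_deg: float, width: float, n_a: int,
                     n_z: int, centre_y: float, convex_out: bool):
    # axis along z through (0, centre_y); surface points straddle the top
    alphas = np.radians(np.linspace(-arc_deg / 2, arc_deg / 2, n_a + 1))
    zs = np.linspace(-width / 2, width / 2, n_z + 1)
    A, Z = np.meshgrid(alphas, zs, indexing="ij")
    vertices = np.column_stack([
        radius * np.sin(A).ravel(),
        centre_y + radius * np.cos(A).ravel(),
        Z.ravel(),
    ])
    faces = []
    for i in range(n_a):
        for j in range(n_z):
            a = i * (n_z + 1) + j
            b = (i + 1) * (n_z + 1) + j
            faces.append((a, a + 1, b))
            faces.append((a + 1, b + 1, b))
    faces = np.asarray(faces, dtype=np.int64)
    if not convex_out:
        faces = faces[:, ::-1]
    return vertices, faces


def _plate_attachments(extent: float, y_top: float):
    h = 15.0  # fixed-side points this far above the joint line
    x = 0.4 * extent
    z = 0.4 * extent
    seg = np.array([[0.0, 0.0, -2.0], [0.0, 0.0, 2.0]])
    out = {}
    for name, sx, sz in (
        ("anterior_tibiotalar", +x, -z),
        ("posterior_tibiotalar", -x, -z),
        ("anterior_talofibular", +x, +z),
        ("posterior_talofibular", -x, +z),
    ):
        p = np.array([sx, 0.0, sz])
        out[name] = (p + seg, p + seg + np.array([0.0, y_top + h, 0.0]))
    return out


def make_joint(spec: FixtureSpec) -> JointFixture:
    """Generate the (talus, tibia, axis, ligament attachments) fixture."""
    n = max(2, int(np.ceil(np.sqrt(spec.resolution / 2))))
    meta: dict = {"spec": spec}

    if spec.kind in ("flat_congruent", "flat_with_depressions"):
        tv, tf = _grid_plate(spec.extent, n, 0.0, up=True)
        bv, bf = _grid_plate(spec.extent, n, spec.gap, up=False)
        if spec.kind == "flat_with_depressions":
            raised = np.zeros(len(bv), dtype=bool)
            for (cx, cz), radius, depth in spec.depressions:
                inside = (bv[:, 0] - cx) ** 2 + (bv[:, 2] - cz) ** 2 <= radius**2
                bv[inside, 1] += depth
                raised |= inside
            # faces with >= 2 raised vertices exceed gap + 2/3*depth at the
            # centroid; with default depths this is the over-threshold set
            n_raised = raised[bf].sum(axis=1)
            meta["depression_face_ids"] = np.flatnonzero(n_raised >= 2)
            meta["depression_core_ids"] = np.flatnonzero(n_raised == 3)
        talus = TriSurface(tv, tf)
        tibia = TriSurface(bv, bf)
        axis = JointAxis(point=(0.0, spec.gap, 0.0), direction=(0.0, 0.0, 1.0))
        attachments = _plate_attachments(spec.extent, spec.gap)
    else:
        r_tal = spec.radius_talus
        if spec.kind == "cylinder_congruent":
            r_tib = r_tal + spec.gap
            tib_centre_y = -r_tal
        else:
            r_tib = float(spec.radius_tibia)  # validated > r_tal + gap
            tib_centre_y = -r_tal + (r_tal + spec.gap) - r_tib
        # talar axis through (0, -r_tal, 0) so the apex sits at y = 0
        tv, tf = _cylinder_sector(r_tal, spec.arc_deg, spec.width, n, n,
                                  centre_y=-r_tal, convex_out=True)
        tib_arc = min(spec.arc_deg + 30.0, 175.0)
        bv, bf = _cylinder_sector(r_tib, tib_arc, spec.width, n, n,
                                  centre_y=tib_centre_y, convex_out=False)
        talus = TriSurface(tv, tf)
        tibia = TriSurface(bv, bf)
        axis = JointAxis(point=(0.0, -r_tal, 0.0), direction=(0.0, 0.0, 1.0))
        half_chord = r_tal * np.sin(np.radians(spec.arc_deg / 2))
        attachments = _plate_attachments(2.5 * half_chord, spec.gap)
        meta["radial_gap"] = (r_tib - r_tal if spec.kind == "cylinder_congruent"
                              else None)
    return JointFixture(talus=talus, tibia=tibia, axis=axis,
                        attachments=attachments, meta=meta)


# ---------------------------------------------------------------------------
# load profiles
# ---------------------------------------------------------------------------

#: duration of the modelled stance phase (s); 65 frames at 0.01 s
STANCE_DURATION_S = 0.64


def load_table1() -> pd.DataFrame:
    """The packaged seven-row stance table (percent, angle, ML/PA/SI force)."""
    with resources.files("ankledem.data").joinpath("table1_stance.csv").open() as f:
        return pd.read_csv(f)


def make_gait_profile(
    n_frames: int,
    peak_force: float = 2000.0,
    peak_angle: float = 15.0,
    shape: str = "half_sine",
    seed: int = 0,
):
    """Generate a stance-like series of :class:`~ankledem.stance.LoadFrame`.

    half_sine : force magnitude peak_force * sin(pi * k/(n-1)) along the
        superior (+y) axis, angle ramping linearly 0 -> peak_angle.
    table1_like : piecewise-linear interpolation of the packaged table over
        percent-stance, with all three force components scaled so the peak
        superior force equals ``peak_force``; angles as tabulated.

    Deterministic; ``seed`` is accepted for interface symmetry.
    """
    from .stance import ColumnMap, LoadFrame

    if n_frames < 3:
        raise ValueError("n_frames must be at least 3")
    frames = []
    if shape == "half_sine":
        times = np.linspace(0.0, STANCE_DURATION_S, n_frames)
        mags = peak_force * np.sin(np.pi * np.arange(n_frames) / (n_frames - 1))
        angles = np.linspace(0.0, peak_angle, n_frames)
        for t, F, a in zip(times, mags, angles):
            frames.append(LoadFrame(time=float(t), angle_deg=float(a),
                                    force=np.array([0.0, F, 0.0])))
    elif shape == "table1_like":
        tab = load_table1()
        pct = np.linspace(tab.percent_stance.iloc[0],
                          tab.percent_stance.iloc[-1], n_frames)
        scale = peak_force / tab.force_si_N.max()
        angle = np.interp(pct, tab.percent_stance, tab.angle_deg)
        ml = np.interp(pct, tab.percent_stance, tab.force_ml_N) * scale
        pa = np.interp(pct, tab.percent_stance, tab.force_pa_N) * scale
        si = np.interp(pct, tab.percent_stance, tab.force_si_N) * scale
        cmap = ColumnMap()
        for p, a, f_ml, f_pa, f_si in zip(pct, angle, ml, pa, si):
            frames.append(LoadFrame(
                time=float(p), angle_deg=float(a),
                force=cmap.to_anatomical(f_ml, f_pa, f_si),
            ))
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    return frames
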