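"""Ankle ligaments as bundles of tension-only linear fibres.

Four bundles (anterior/posterior tibiotalar, anterior/posterior
talofibular) stabilise the talus against translation.  Each fibre is a
linear spring of modulus E (default 255 MPa) and cross-section
``fibre_area`` acting only in tension:

    T = (E * A / L0) * max(L - L0, 0)

with L0 the rest length captured at the reference pose (no pre-strain) and
L the current length after the talus-side endpoint translates with the
talus.  The force on the talus is directed along the current fibre line,
pulling it toward the fixed (tibia/fibula-side) endpoint; the consistent
tangent of all taut fibres feeds the equilibrium solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger("ankledem.ligaments")

BUNDLE_NAMES = (
    "anterior_tibiotalar",
    "posterior_tibiotalar",
    "anterior_talofibular",
    "posterior_talofibular",
)


@dataclass(frozen=True)
class LigamentBundle:
    """A bundle of parallel fibres between two attachment footprints."""

    name: str
    talus_points: np.ndarray  # (f, 3) mm, talus-side attachments at reference
    fixed_points: np.ndarray  # (f, 3) mm, tibia/fibula-side attachments
    E: float                  # MPa
    fibre_area: float         # mm^2 per fibre
    rest_lengths: np.ndarray  # (f,) mm

    def __post_init__(self):
        tp = np.atleast_2d(np.asarray(self.talus_points, dtype=float))
        fp = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        rl = np.atleast_1d(np.asarray(self.rest_lengths, dtype=float))
        if len(tp) == 0:
            raise ValueError(f"{self.name}: bundle needs at least one fibre")
        if tp.shape != fp.shape or len(rl) != len(tp):
            raise ValueError(f"{self.name}: inconsistent fibre arrays")
        if (rl <= 0).any():
            raise ValueError(f"{self.name}: coincident endpoints (zero rest length)")
        if self.E <= 0 or self.fibre_area <= 0:
            raise ValueError(f"{self.name}: E and fibre_area must be positive")
        object.__setattr__(self, "talus_points", tp)
        object.__setattr__(self, "fixed_points", fp)
        object.__setattr__(self, "rest_lengths", rl)

    @property
    def n_fibres(self) -> int:
        return len(self.rest_lengths)

    def with_fixed_points(self, fixed_points: np.ndarray) -> "LigamentBundle":
        """Re-pose the fixed-side endpoints (rest lengths are unchanged)."""
        return replace(self, fixed_points=np.atleast_2d(np.asarray(fixed_points, float)))


def _as_segment(endpoint) -> np.ndarray:
    pts = np.asarray(endpoint, dtype=float)
    if pts.ndim == 1:
        pts = np.stack([pts, pts])
    return pts


def make_bundles(
    attachments: dict,
    material=None,
    fibre_area: float = 1.0,
    fibres_per_bundle: int = 5,
    E: float | None = None,
) -> list[LigamentBundle]:
    """Build ligament bundles from per-bundle attachment footprints.

    ``attachments`` maps a bundle name to a ``(talus_side, fixed_side)``
    pair; each side is a single 3-point or a 2x3 segment.  Fibres are
    spread evenly along both footprints; rest lengths are the endpoint
    distances at this (reference) pose.  Fewer than four bundles is allowed
    but warned about.
    """
    if E is None:
        E = material.E_ligament if material is not None else 255.0
    if fibres_per_bundle < 1:
        raise ValueError("fibres_per_bundle must be >= 1")
    if len(attachments) < 4:
        logger.warning("only %d ligament bundle(s) supplied (expected 4)",
                       len(attachments))
    bundles = []
    for name, (talus_side, fixed_side) in attachments.items():
        tseg = _as_segment(talus_side)
        fseg = _as_segment(fixed_side)
        if fibres_per_bundle == 1:
            fracs = np.array([0.5])
        else:
            fracs = np.linspace(0.0, 1.0, fibres_per_bundle)
        tp = tseg[0] + fracs[:, None] * (tseg[1] - tseg[0])
        fp = fseg[0] + fracs[:, None] * (fseg[1] - fseg[0])
        rl = np.linalg.norm(fp - tp, axis=1)
        if (rl <= 0).any():
            raise ValueError(f"{name}: coincident endpoints (zero rest length)")
        bundles.append(
            LigamentBundle(
                name=name, talus_points=tp, fixed_points=fp,
                E=E, fibre_area=fibre_area, rest_lengths=rl,
            )
        )
    return bundles


def with_modulus(bundles: list[LigamentBundle], E: float) -> list[LigamentBundle]:
    """Same geometry, different Young's modulus (sensitivity sweeps)."""
    return [replace(b, E=E) for b in bundles]


def ligament_forces(
    bundles: list[LigamentBundle] | None,
    u,
    tension_only: bool = True,
):
    """Total ligament force on the talus at translation ``u`` from reference.

    Returns ``(force, tensions, K)``:

    force : (3,) N — sum over fibres of T * d_hat, pulling the talus toward
        the fixed side (this is the force the ligaments exert *on* the talus).
    tensions : (f_total,) N per fibre, in bundle order.
    K : (3, 3) N/mm — symmetric tangent stiffness of the taut fibres
        (material term (EA/L0) d d^T plus geometric term (T/L)(I - d d^T)),
        i.e. minus the derivative of ``force`` with respect to ``u``.
    """
    u = np.asarray(u, dtype=float).reshape(3)
    force = np.zeros(3)
    K = np.zeros((3, 3))
    tensions = []
    if not bundles:
        return force, np.zeros(0), K
    for b in bundles:
        d = b.fixed_points - (b.talus_points + u)  # talus -> fixed
        L = np.linalg.norm(d, axis=1)
        if (L <= 0).any():
            raise ValueError(f"{b.name}: fibre collapsed to zero length")
        dhat = d / L[:, None]
        stretch = L - b.rest_lengths
        kf = b.E * b.fibre_area / b.rest_lengths  # N/mm per fibre
        if tension_only:
            T = kf * np.maximum(stretch, 0.0)
            taut = stretch > 0
        else:
            T = kf * stretch
            taut = np.ones_like(stretch, dtype=bool)
        tensions.append(T)
        force += dhat.T @ T
        for j in np.flatnonzero(taut):
            dd = np.outer(dhat[j], dhat[j])
            K += kf[j] * dd + (T[j] / L[j]) * (np.eye(3) - dd)
    return force, np.concatenate(tensions), K
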