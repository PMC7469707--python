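"""Translation-only contact equilibrium of the talus on the spring bed.

At each time point the talus, loaded by the joint contact force F, is in
static equilibrium against the spring mattress and the ligaments.  With
n_i the unit spring direction (talar normal, pointing toward the tibia)
and u the talus translation increment, each nominal spring carries

    f_i = k_i (n_i . u) + f_prev_i          (extended DEM)
    f_i = k_i (n_i . u)                     (classical DEM, f_prev = 0)

where f_prev_i >= 0 is the push-back force stored from the previous time
point.  A positive f_i is compression: the spring pushes the talus back
along -n_i.  Writing G(v) for the force the ligaments exert on the talus
at cumulative translation v, equilibrium reads

    F - sum_i f_i n_i + G(u_cum + u) = 0   on the active set.

The 3x3 system K u = rhs (K = sum k_i n_i n_i^T + K_lig) is solved with
Newton iterations (the ligaments are tension-only, hence piecewise
linear); springs driven into tension (f_i <= 0) are released and the
solve repeats on the reduced set until only compressed springs remain —
the active contact region.  Contact pressure is f_i / A_i.

The extended variant carries state between time points (cumulative talus
translation and the stored per-spring forces); the classical variant is
stateless and never moves the talus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ligaments import LigamentBundle, ligament_forces
from .mattress import SpringMattress, SpringStatus

logger = logging.getLogger("ankledem.solver")

_MAX_NEWTON = 60


class SolverError(RuntimeError):
    """Base class for equilibrium failures."""


class UnderConstrainedError(SolverError):
    """The load has a component no spring/ligament direction can balance."""


class LiftOffError(SolverError):
    """All springs released but the load is not balanced by ligaments alone."""


class IterationLimitError(SolverError):
    """The active-set (or Newton) iteration cap was reached."""


@dataclass
class SolverParams:
    """Numerical controls for the equilibrium solve.

    residual_tol : N; default 1e-8 * max(1, ||F||) per solve.
    max_active_set_iterations : default = initial nominal spring count.
    stiffness_update : 'lagged' holds k_i at the start-of-step gap (the
        gap is refreshed only between time points); 'within_step'
        recomputes k_i from the deformed gap each active-set iteration.
    removal_rule : 'all_tensile' drops every non-compressed spring per
        iteration; 'most_tensile_only' drops one.
    """

    residual_tol: float | None = None
    max_active_set_iterations: int | None = None
    stiffness_update: str = "lagged"
    removal_rule: str = "all_tensile"
    ligaments_in_balance: bool = True
    tension_only_ligaments: bool = True

    def __post_init__(self):
        if self.residual_tol is not None and self.residual_tol <= 0:
            raise ValueError("residual_tol must be positive")
        if (self.max_active_set_iterations is not None
                and self.max_active_set_iterations < 1):
            raise ValueError("max_active_set_iterations must be >= 1")
        if self.stiffness_update not in ("lagged", "within_step"):
            raise ValueError("stiffness_update must be 'lagged' or 'within_step'")
        if self.removal_rule not in ("all_tensile", "most_tensile_only"):
            raise ValueError(
                "removal_rule must be 'all_tensile' or 'most_tensile_only'")


@dataclass
class SolverState:
    """Carried between time points: cumulative talus translation and the
    stored (push-back) spring forces f_{t-1} >= 0."""

    u_cum: np.ndarray          # (3,) mm
    stored_forces: np.ndarray  # (m,) N

    @classmethod
    def zero(cls, n_springs: int) -> "SolverState":
        return cls(u_cum=np.zeros(3), stored_forces=np.zeros(n_springs))

    def copy(self) -> "SolverState":
        return SolverState(self.u_cum.copy(), self.stored_forces.copy())


@dataclass
class ContactSolution:
    """Equilibrium result for one time point."""

    active_ids: np.ndarray     # triangle indices in compression
    spring_forces: np.ndarray  # N, aligned with active_ids (all > 0)
    pressures: np.ndarray      # MPa, aligned with active_ids
    u_step: np.ndarray         # (3,) mm translation increment of this solve
    residual: np.ndarray       # (3,) N
    iterations: int            # active-set iterations


def _lstsq3(K: np.ndarray, r: np.ndarray) -> np.ndarray:
    # minimum-norm Newton step; K may be rank-deficient (e.g. parallel
    # springs, no ligaments) and the load still consistent
    return np.linalg.lstsq(K, r, rcond=None)[0]


def _solve_core(
    mattress: SpringMattress,
    bundles: list[LigamentBundle] | None,
    F_applied,
    stored: np.ndarray,
    u_cum: np.ndarray,
    params: SolverParams,
):
    F = np.asarray(F_applied, dtype=float).reshape(3)
    if not np.all(np.isfinite(F)):
        raise ValueError("applied force must be finite")
    use_lig = params.ligaments_in_balance and bundles

    def lig(v):
        if not use_lig:
            return np.zeros(3), np.zeros((3, 3))
        G, _, K = ligament_forces(bundles, v,
                                  tension_only=params.tension_only_ligaments)
        return G, K

    tol = params.residual_tol
    if tol is None:
        tol = 1e-8 * max(1.0, float(np.linalg.norm(F)))

    nominal = np.flatnonzero(mattress.status == int(SpringStatus.NOMINAL))
    m_nom = len(nominal)

    # truly trivial problem: no load, no stored push-back, no ligament pull
    G0, _ = lig(u_cum)
    if (np.linalg.norm(F) == 0.0
            and (m_nom == 0 or not (stored[nominal] > 0).any())
            and np.linalg.norm(G0) <= tol):
        empty = np.zeros(0)
        status = mattress.status
        status[nominal] = int(SpringStatus.ACTIVE)
        sol = ContactSolution(
            active_ids=nominal.copy(),
            spring_forces=np.zeros(m_nom),
            pressures=np.zeros(m_nom),
            u_step=np.zeros(3),
            residual=F.copy(),
            iterations=0,
        )
        # zero-load success: forces are zero; treat full nominal set as the
        # (unloaded) active set so pressure maps report zeros there
        return sol, np.zeros(3)

    max_as = params.max_active_set_iterations or max(m_nom, 1)

    S = nominal.copy()
    u = np.zeros(3)
    iterations = 0
    r = F.copy()
    while True:
        iterations += 1
        if iterations > max_as + 1:
            raise IterationLimitError(
                f"active-set iteration cap {max_as} reached")
        n = mattress.directions[S]
        fprev = stored[S]
        if params.stiffness_update == "within_step":
            h = mattress.lengths[S] - n @ u
            h = np.maximum(h, 1e-6)
            from .mattress import poisson_factor
            k = (poisson_factor(mattress.material.nu)
                 * mattress.material.E_cartilage * mattress.areas[S] / h)
        else:
            k = mattress.stiffness[S]

        # Newton on u (piecewise linear because of tension-only ligaments)
        converged = False
        for _ in range(_MAX_NEWTON):
            f = k * (n @ u) + fprev if len(S) else np.zeros(0)
            G, Klig = lig(u_cum + u)
            r = F - (n.T @ f if len(S) else 0.0) + G
            if np.linalg.norm(r) <= tol:
                converged = True
                break
            K = Klig.copy()
            if len(S):
                K += (n.T * k) @ n
            du = _lstsq3(K, r)
            if not np.all(np.isfinite(du)) or np.linalg.norm(du) == 0.0:
                break
            u = u + du
        if not converged:
            if len(S) == 0:
                raise LiftOffError(
                    "all springs released and ligaments cannot balance the load")
            rank = np.linalg.matrix_rank(
                (n.T * k) @ n + lig(u_cum + u)[1], tol=1e-12)
            if rank < 3:
                raise UnderConstrainedError(
                    "equilibrium residual cannot be reduced: fewer than 3 "
                    "independent spring/ligament directions")
            raise IterationLimitError("Newton iteration failed to converge")

        f = k * (n @ u) + fprev if len(S) else np.zeros(0)
        tensile = f <= 0.0
        if not tensile.any():
            break
        if params.removal_rule == "most_tensile_only":
            drop = np.array([np.argmin(f)])
        else:
            drop = np.flatnonzero(tensile)
        mattress.status[S[drop]] = int(SpringStatus.RELEASED)
        keep = np.ones(len(S), dtype=bool)
        keep[drop] = False
        S = S[keep]
        if len(S) == 0:
            # uniform-unload limit: all spring forces passed through zero
            # together; accept if the ligaments (or nothing) balance the load
            G, _ = lig(u_cum + u)
            r = F + G
            if np.linalg.norm(r) <= tol:
                break
            # otherwise one last Newton attempt with ligaments only happens
            # on the next loop pass
    # final bookkeeping
    n = mattress.directions[S]
    if params.stiffness_update == "within_step":
        h = mattress.lengths[S] - n @ u
        h = np.maximum(h, 1e-6)
        from .mattress import poisson_factor
        k_fin = (poisson_factor(mattress.material.nu)
                 * mattress.material.E_cartilage * mattress.areas[S] / h)
    else:
        k_fin = mattress.stiffness[S]
    forces = k_fin * (n @ u) + stored[S] if len(S) else np.zeros(0)
    pressures = forces / mattress.areas[S] if len(S) else np.zeros(0)
    mattress.status[S] = int(SpringStatus.ACTIVE)
    G, _ = lig(u_cum + u)
    residual = F - (n.T @ forces if len(S) else 0.0) + G
    logger.debug(
        "solve: %d active / %d nominal, %d iteration(s), |r|=%.3e N",
        len(S), m_nom, iterations, float(np.linalg.norm(residual)),
    )
    sol = ContactSolution(
        active_ids=S,
        spring_forces=forces,
        pressures=pressures,
        u_step=u.copy(),
        residual=residual,
        iterations=iterations,
    )
    return sol, u


def solve_equilibrium_edem(
    mattress: SpringMattress,
    bundles: list[LigamentBundle] | None,
    F_applied,
    state: SolverState,
    params: SolverParams | None = None,
):
    """Extended-DEM solve: push-back forces enter the balance and the talus
    translation accumulates.

    Returns ``(solution, new_state)``; ``new_state.u_cum`` includes this
    step's increment and ``new_state.stored_forces`` holds f_t for active
    springs and zero for all others.
    """
    params = params or SolverParams()
    sol, u = _solve_core(
        mattress, bundles, F_applied, state.stored_forces, state.u_cum, params
    )
    stored = np.zeros(mattress.n_springs)
    stored[sol.active_ids] = sol.spring_forces
    new_state = SolverState(u_cum=state.u_cum + u, stored_forces=stored)
    return sol, new_state


def solve_equilibrium_dem(
    mattress: SpringMattress,
    bundles: list[LigamentBundle] | None,
    F_applied,
    params: SolverParams | None = None,
) -> ContactSolution:
    """Classical-DEM solve: stateless (f_prev = 0, talus never displaced).

    The displacement is relative to the reference position and is used only
    to evaluate the spring forces, never to move the bone.
    """
    params = params or SolverParams()
    sol, _ = _solve_core(
        mattress, bundles, F_applied,
        np.zeros(mattress.n_springs), np.zeros(3), params,
    )
    return sol


def pressure_map(solution: ContactSolution, mattress: SpringMattress):
    """Per-triangle pressure field plus (peak MPa, active area cm^2).

    Non-active triangles carry zero pressure; the active area is the sum of
    the active triangle areas (1 cm^2 = 100 mm^2).
    """
    pressures = np.zeros(mattress.n_springs)
    pressures[solution.active_ids] = solution.pressures
    loaded = solution.active_ids[solution.spring_forces > 0]
    area_cm2 = float(mattress.areas[loaded].sum()) / 100.0
    peak = float(pressures.max()) if len(pressures) else 0.0
    return pressures, peak, area_cm2


def advance_state(state: SolverState, solution: ContactSolution,
                  mattress: SpringMattress) -> SolverState:
    """Prepare the next time point: store f_t on active springs, zero the
    rest, and make every spring available again for contact.

    ``state.u_cum`` was already updated by the solver; statuses are reset
    in place (released/over-threshold -> nominal; absent stays absent).
    """
    stored = np.zeros(mattress.n_springs)
    stored[solution.active_ids] = solution.spring_forces
    present = mattress.status != int(SpringStatus.ABSENT)
    mattress.status[present] = int(SpringStatus.NOMINAL)
    return SolverState(u_cum=state.u_cum.copy(), stored_forces=stored)
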