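"""Quasi-static sagittal-plane equilibrium of the ligamentous spine.

A deliberately desk-scale surrogate for a continuum finite-element run:
three sagittal rotational unknowns (θ at C0–C1, C1–C2, C2–C3), tension-only
ligament springs, a compressive preload acting through a configurable
anterior lever arm at the occiput, unilateral rotational stops standing in
for bony facet contact, and regularized Coulomb facet friction.  The
solver finds the joint angles zeroing the net sagittal moment at every
joint under an applied occipital moment.  It is validated against the
one-torsional-spring closed form and by mechanical properties (monotone
moment-rotation, monotone softening, work-energy balance); no claim is
made that it reproduces continuum-model angles.

Sign convention: flexion positive, moments in N·mm, angles internally in
radians (reported in degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import (
    ContactSpec,
    Direction,
    Joint,
    LigamentSpec,
    LoadCase,
    SpineModel,
    Vertebra,
)

__all__ = [
    "SolverConfig",
    "EquilibriumState",
    "solve_static",
    "moment_sweep",
    "energy_balance",
]

_JOINTS = (Joint.C0C1, Joint.C1C2, Joint.C2C3)
_Y = np.array([0.0, 1.0, 0.0])


def _smooth_ramp(x, eps: float):
    """C¹ regularization of max(x, 0) with the consistent antiderivative.

    Returns (phi, Phi): phi = 0 for x <= 0, x²/(2ε) on (0, ε),
    x − ε/2 beyond; Phi is its integral (so forces stay the exact
    gradient of the stored energy).  ε is tiny relative to physical
    elongations; it only removes the taut/slack kink for the solver.
    """
    x = np.asarray(x, dtype=float)
    phi = np.where(x <= 0, 0.0, np.where(x < eps, x**2 / (2 * eps), x - eps / 2))
    Phi = np.where(
        x <= 0,
        0.0,
        np.where(
            x < eps,
            x**3 / (6 * eps),
            x**2 / 2 - eps * x / 2 + eps**2 / 6,
        ),
    )
    return phi, Phi


@dataclass
class SolverConfig:
    """Numerical and surrogate-contact parameters.

    ``stop_angle_deg`` is the unilateral rotational stop standing in for
    bony end range (per joint, symmetric); ``facet_radius_mm`` converts
    the published 0.01-mm joint clearance into an engagement angle;
    ``friction_radius_mm`` is the effective moment arm of facet friction;
    ``preload_lever_mm`` places the preload line of action anterior to the
    joint centres (the head's centre of gravity is not published, so this
    is a template choice).  ``friction_reg_deg`` is the tanh
    regularization scale of the Coulomb law.
    """

    stop_angle_deg: float = 20.0
    stop_stiffness_Nmm_per_rad: float = 5.0e4
    facet_radius_mm: float = 30.0
    friction_radius_mm: float = 5.0
    preload_lever_mm: float = 10.0
    friction_reg_deg: float = 0.02
    tension_reg_mm: float = 1e-3
    stop_reg_rad: float = 1e-4
    tol_Nmm: float = 1e-6
    max_iter: int = 100
    fd_step_rad: float = 1e-7


@dataclass
class EquilibriumState:
    """Converged configuration under one applied moment."""

    applied_moment_Nmm: float
    angles_deg: dict[Joint, float]
    ligament_state: dict[str, tuple[float, float]]  # name -> (dl mm, F N)
    contact_engaged: dict[Joint, bool]
    residual_Nmm: dict[Joint, float]
    elastic_energy_Nmm: float
    friction_torque_Nmm: dict[Joint, float]
    preload_point_mm: np.ndarray
    total_rotation_deg: float

    @property
    def n_engaged_contacts(self) -> int:
        return sum(self.contact_engaged.values())


class _Mechanics:
    """Precomputed geometry and residual evaluation for one scenario."""

    def __init__(
        self,
        model: SpineModel,
        specs: list[LigamentSpec],
        load: LoadCase,
        stiffness_scale: float,
        contact: ContactSpec,
        config: SolverConfig,
        torsional_stiffness: dict[Joint, float] | None,
    ) -> None:
        if stiffness_scale <= 0:
            raise ValueError("stiffness scale must be positive")
        self.model = model
        self.specs = specs
        self.load = load
        self.scale = stiffness_scale
        self.contact = contact
        self.cfg = config
        self.tors = {
            j: stiffness_scale * k for j, k in (torsional_stiffness or {}).items()
        }
        self.centers = {j: model.joint_centers_world[j] for j in _JOINTS}
        # Neutral attachment coordinates and the chain level of each endpoint.
        self.p0 = np.array(
            [model.attachment_world(*s.origin) for s in specs]
        ).reshape(-1, 3)
        self.p1 = np.array(
            [model.attachment_world(*s.insertion) for s in specs]
        ).reshape(-1, 3)
        self.lv0 = np.array([s.origin[0].level for s in specs], dtype=int)
        self.lv1 = np.array([s.insertion[0].level for s in specs], dtype=int)
        self.L0 = np.array([s.rest_length_L0 for s in specs])
        self.k = stiffness_scale * np.array([s.rigidity_k for s in specs])
        c0 = model.vertebrae[Vertebra.C0]
        self.p_load_neutral = c0.origin_world + np.array(
            [config.preload_lever_mm, 0.0, 5.0]
        )
        self.theta_stop = np.deg2rad(config.stop_angle_deg)
        self.theta_reg = np.deg2rad(config.friction_reg_deg)
        self.theta_clear = contact.clearance_mm / config.facet_radius_mm

    # -- kinematics -----------------------------------------------------
    def _rotations(self, theta: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Per-level (R, t) mapping neutral coordinates to the deformed state.

        Level 3 (base) is identity; level l composes the joint rotations
        below C(l) bottom-up about the (current) joint centres.
        """
        out: dict[int, tuple[np.ndarray, np.ndarray]] = {
            3: (np.eye(3), np.zeros(3))
        }
        for joint, th in zip((Joint.C2C3, Joint.C1C2, Joint.C0C1), theta[::-1]):
            Rl, tl = out[joint.lower.level]
            c, s = np.cos(th), np.sin(th)
            Rj = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
            cj = self.centers[joint]
            R = Rl @ Rj
            t = Rl @ (cj - Rj @ cj) + tl
            out[joint.upper.level] = (R, t)
        return out

    def _point(self, frames, level: int, p: np.ndarray) -> np.ndarray:
        R, t = frames[level]
        return R @ p + t

    # -- residual -------------------------------------------------------
    def evaluate(self, theta: np.ndarray) -> dict:
        """Net sagittal moment per joint plus state bookkeeping.

        theta is (θ_C0C1, θ_C1C2, θ_C2C3) in radians.  The residual at
        joint j is the total Y-moment, about the current joint centre, of
        everything acting on the super-body above j: the applied couple,
        the preload force, spanning-ligament tensions, the rotational stop
        and regularized Coulomb friction.
        """
        cfg = self.cfg
        frames = self._rotations(theta)
        # Deformed attachment points.
        q0 = np.array(
            [self._point(frames, lv, p) for lv, p in zip(self.lv0, self.p0)]
        ).reshape(-1, 3)
        q1 = np.array(
            [self._point(frames, lv, p) for lv, p in zip(self.lv1, self.p1)]
        ).reshape(-1, 3)
        d = q1 - q0
        length = np.linalg.norm(d, axis=1)
        dl = length - self.L0
        phi, Phi = _smooth_ramp(dl, cfg.tension_reg_mm)
        F = self.k * phi  # tension only (C¹-regularized at the kink)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(length[:, None] > 0, d / length[:, None], 0.0)

        p_load = self._point(frames, 0, self.p_load_neutral)
        F_pre = np.array([0.0, 0.0, -self.load.preload_F])

        M_applied = self.load.signed_moment
        residual = np.zeros(3)
        fric = np.zeros(3)
        engaged = {}
        for i, joint in enumerate(_JOINTS):
            cj = self._point(frames, joint.lower.level, self.centers[joint])
            m = M_applied
            # Preload (acts on C0, always above every joint).
            m += float(np.cross(p_load - cj, F_pre) @ _Y)
            # Spanning ligaments: tension pulls the upper-chain endpoint
            # toward the lower one.
            for li in range(len(self.specs)):
                lo = min(self.lv0[li], self.lv1[li])
                hi = max(self.lv0[li], self.lv1[li])
                if not (lo <= joint.upper.level and joint.lower.level <= hi):
                    continue
                if F[li] == 0.0:
                    continue
                if self.lv0[li] <= joint.upper.level:
                    p_up, f_vec = q0[li], F[li] * unit[li]
                else:
                    p_up, f_vec = q1[li], -F[li] * unit[li]
                m += float(np.cross(p_up - cj, f_vec) @ _Y)
            # Torsional spring (oracle hook / lumped-stiffness use).
            if joint in self.tors:
                m -= self.tors[joint] * theta[i]
            # Unilateral rotational stop (C¹-regularized).
            exc = abs(theta[i]) - self.theta_stop
            sphi, _ = _smooth_ramp(exc, cfg.stop_reg_rad)
            m -= np.sign(theta[i]) * cfg.stop_stiffness_Nmm_per_rad * float(sphi)
            # Regularized Coulomb facet friction, normal load = preload.
            tau_f = (
                -self.contact.friction_mu
                * self.load.preload_F
                * cfg.friction_radius_mm
                * np.tanh(theta[i] / self.theta_reg)
            )
            m += tau_f
            fric[i] = tau_f
            residual[i] = m
            engaged[joint] = bool(abs(theta[i]) > self.theta_clear or exc > 0)

        elastic = float(np.sum(self.k * Phi))
        for i, joint in enumerate(_JOINTS):
            if joint in self.tors:
                elastic += 0.5 * self.tors[joint] * theta[i] ** 2
            exc = abs(theta[i]) - self.theta_stop
            _, sPhi = _smooth_ramp(exc, cfg.stop_reg_rad)
            elastic += cfg.stop_stiffness_Nmm_per_rad * float(sPhi)
        return {
            "residual": residual,
            "dl": dl,
            "F": F,
            "engaged": engaged,
            "friction": fric,
            "elastic": elastic,
            "p_load": p_load,
        }

    def residual(self, theta: np.ndarray) -> np.ndarray:
        return self.evaluate(theta)["residual"]


def _newton(mech: _Mechanics, theta0: np.ndarray) -> np.ndarray:
    """Damped Newton on the stacked residual; scipy root as fallback."""
    cfg = mech.cfg
    theta = theta0.astype(float).copy()
    r = mech.residual(theta)
    for _ in range(cfg.max_iter):
        if np.max(np.abs(r)) <= cfg.tol_Nmm:
            return theta
        J = np.empty((3, 3))
        h = cfg.fd_step_rad
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            J[:, j] = (mech.residual(theta + e) - mech.residual(theta - e)) / (2 * h)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        norm0 = np.linalg.norm(r)
        for _ in range(40):
            trial = theta + lam * step
            r_trial = mech.residual(trial)
            if np.linalg.norm(r_trial) < norm0:
                theta, r = trial, r_trial
                break
            lam *= 0.5
        else:
            break
    if np.max(np.abs(r)) <= cfg.tol_Nmm:
        return theta
    sol = optimize.root(mech.residual, theta, method="hybr", tol=1e-12)
    theta = sol.x
    r = mech.residual(theta)
    if np.max(np.abs(r)) > cfg.tol_Nmm:
        raise RuntimeError(
            f"equilibrium solver did not converge: residuals {r} N·mm"
        )
    return theta


def _continuation(mech_at, theta0: np.ndarray) -> np.ndarray:
    """Solve at increasing load factors, bisecting any step that fails."""
    theta = theta0.astype(float).copy()
    reached = 0.0
    pending = [1.0]
    while pending:
        target = pending[-1]
        try:
            theta = _newton(mech_at(target), theta)
            reached = target
            pending.pop()
        except RuntimeError:
            if target - reached < 1e-3:
                raise
            pending.append(0.5 * (reached + target))
    return theta


def _multistart(mech: _Mechanics, theta0: np.ndarray) -> np.ndarray:
    """Root search from a grid of starts; nearest converged root wins."""
    cfg = mech.cfg
    marks = (0.0, -1.05 * mech.theta_stop, 1.05 * mech.theta_stop)
    best: np.ndarray | None = None
    best_dist = np.inf
    starts = [theta0] + [
        np.array(g) for g in np.stack(
            np.meshgrid(marks, marks, marks), axis=-1
        ).reshape(-1, 3)
    ]
    for guess in starts:
        sol = optimize.root(mech.residual, guess, method="hybr", tol=1e-12)
        r = mech.residual(sol.x)
        if np.max(np.abs(r)) <= cfg.tol_Nmm:
            dist = float(np.linalg.norm(sol.x - theta0))
            if dist < best_dist:
                best, best_dist = sol.x, dist
    if best is None:
        raise RuntimeError(
            "equilibrium solver did not converge from any start "
            f"(residual at warm start: {mech.residual(theta0)} N·mm)"
        )
    return best


def solve_static(
    model: SpineModel,
    specs: list[LigamentSpec],
    load: LoadCase,
    stiffness_scale: float = 1.0,
    contact: ContactSpec | None = None,
    config: SolverConfig | None = None,
    torsional_stiffness: dict[Joint, float] | None = None,
    theta0_deg: dict[Joint, float] | None = None,
) -> EquilibriumState:
    """Solve the three joint angles zeroing the net sagittal moments.

    ``torsional_stiffness`` (N·mm/rad per joint) adds lumped rotational
    springs — with no ligaments it reduces to the closed form θ = M/k_θ
    used as the solver oracle.  ``stiffness_scale`` multiplies every
    spring stiffness (< 1 encodes ligament fatigue).

    Raises
    ------
    RuntimeError
        On non-convergence (with the residual report).
    ValueError
        For a non-positive stiffness scale.
    """
    contact = contact or ContactSpec()
    config = config or SolverConfig()

    def mech_at(factor: float) -> _Mechanics:
        scaled = LoadCase(
            preload_F=factor * load.preload_F,
            moment_M=factor * load.moment_M,
            direction=load.direction,
        )
        return _Mechanics(
            model, specs, scaled, stiffness_scale, contact, config,
            torsional_stiffness,
        )

    theta0 = np.zeros(3)
    if theta0_deg:
        theta0 = np.deg2rad(
            np.array([theta0_deg.get(j, 0.0) for j in _JOINTS])
        )
    mech = mech_at(1.0)
    try:
        theta = _newton(mech, theta0)
    except RuntimeError:
        try:
            # Bisection fallback on the load factor: ramp the load and
            # warm-start each sub-step.
            theta = _continuation(mech_at, theta0)
        except RuntimeError:
            # Friction plateaus can hide the root from local iterations
            # entirely (snap-through past a friction-held branch):
            # multistart root search, keeping the converged equilibrium
            # closest to the warm start (the loading branch).
            theta = _multistart(mech, theta0)
    ev = mech.evaluate(theta)
    return EquilibriumState(
        applied_moment_Nmm=load.signed_moment,
        angles_deg={j: float(np.degrees(theta[i])) for i, j in enumerate(_JOINTS)},
        ligament_state={
            s.name: (float(ev["dl"][i]), float(ev["F"][i]))
            for i, s in enumerate(specs)
        },
        contact_engaged=ev["engaged"],
        residual_Nmm={j: float(ev["residual"][i]) for i, j in enumerate(_JOINTS)},
        elastic_energy_Nmm=ev["elastic"],
        friction_torque_Nmm={
            j: float(ev["friction"][i]) for i, j in enumerate(_JOINTS)
        },
        preload_point_mm=ev["p_load"],
        total_rotation_deg=float(np.degrees(theta.sum())),
    )


def moment_sweep(
    model: SpineModel,
    specs: list[LigamentSpec],
    direction: Direction = Direction.FLEXION,
    n_steps: int = 50,
    stiffness_scale: float = 1.0,
    max_moment_Nmm: float = 1500.0,
    preload_F: float = 100.0,
    contact: ContactSpec | None = None,
    config: SolverConfig | None = None,
    torsional_stiffness: dict[Joint, float] | None = None,
) -> list[EquilibriumState]:
    """Quasi-static ramp of the applied moment from 0 to ``max_moment_Nmm``.

    Each state is an independent equilibrium (warm-started from the
    previous step for speed only); under the monotone spring laws the
    sweep is path-independent.

    Raises
    ------
    RuntimeError
        Propagated solver failure, naming the failing step.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 sweep steps")
    moments = np.linspace(0.0, max_moment_Nmm, n_steps)
    states: list[EquilibriumState] = []
    warm: dict[Joint, float] | None = None
    for i, m in enumerate(moments):
        load = LoadCase(preload_F=preload_F, moment_M=float(m), direction=direction)
        try:
            st = solve_static(
                model,
                specs,
                load,
                stiffness_scale=stiffness_scale,
                contact=contact,
                config=config,
                torsional_stiffness=torsional_stiffness,
                theta0_deg=warm,
            )
        except RuntimeError as err:
            raise RuntimeError(f"sweep failed at step {i} (M = {m} N·mm): {err}")
        states.append(st)
        warm = st.angles_deg
    return states


def energy_balance(states: list[EquilibriumState], preload_F: float) -> dict:
    """Work-energy audit of a sweep.

    External work (applied couple through the total occipital rotation,
    plus preload force through its point of application) should equal the
    stored elastic energy change plus frictional dissipation.  Integrals
    use the trapezoid rule over the sweep states.
    """
    W = 0.0
    D = 0.0
    F_pre = np.array([0.0, 0.0, -preload_F])
    for a, b in zip(states[:-1], states[1:]):
        dTheta = np.deg2rad(b.total_rotation_deg - a.total_rotation_deg)
        W += 0.5 * (a.applied_moment_Nmm + b.applied_moment_Nmm) * dTheta
        W += float(F_pre @ (b.preload_point_mm - a.preload_point_mm))
        for j in _JOINTS:
            dth = np.deg2rad(b.angles_deg[j] - a.angles_deg[j])
            tau = 0.5 * (a.friction_torque_Nmm[j] + b.friction_torque_Nmm[j])
            D += -tau * dth  # friction opposes motion -> positive dissipation
    dE = states[-1].elastic_energy_Nmm - states[0].elastic_energy_Nmm
    denom = max(abs(W), abs(dE) + abs(D), 1e-12)
    return {
        "external_work_Nmm": W,
        "elastic_energy_delta_Nmm": dE,
        "friction_dissipation_Nmm": D,
        "relative_imbalance": abs(W - dE - D) / denom,
    }
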