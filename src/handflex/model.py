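"""Core mechanical model of a tendon-driven four-finger hand.

The hand is idealized as four planar kinematic chains (index, middle, ring,
little), each with three torsional joints (MCP, PIP, DIP) connecting rigid
phalanges.  Three extrinsic muscles act on every finger through tendon slips:

* FDS (flexor digitorum superficialis) crosses MCP and PIP,
* FDP (flexor digitorum profundus) crosses MCP, PIP and DIP — the only
  flexor across the DIP,
* ED (extensor digitorum) crosses all three joints with extension
  (negative) moment arms.

Each muscle is displacement-driven: a prescribed muscle–tendon-junction (MTJ)
displacement ``x`` (mm, shortening positive) is shared by the muscle's four
slips.  A slip behaves as a series spring (tendon in series with its
retaining ligament/pulley); its elastic stretch is the applied displacement
minus the geometric tendon excursion ``E(θ) = Σ r_j(θ_j + γθ_j²/2)`` (arms
may grow with flexion at rate γ), and tension is ``k_eff · max(x − E, 0)``
— tendons cannot push.  Joints carry torsional
springs equivalent to three identical linear collateral/dorsal springs at a
lever radius, ``K = 3 k l²``.  Resisted flexion adds a unilateral penalty
contact against a rigid plate.

Units are N–mm–MPa throughout (1 N/mm = 1000 N/m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MUSCLES",
    "FINGERS",
    "JOINTS",
    "ConfigurationError",
    "SolverError",
    "ParameterSet",
    "JointSpec",
    "TendonSlip",
    "Muscle",
    "FingerSpec",
    "HandModel",
    "EquilibriumState",
    "torsional_stiffness_from_linear",
    "rotational_stiffness",
    "tendon_excursion",
    "effective_stiffness",
    "slip_tension",
    "contact_force",
    "residual_torques",
    "solve_equilibrium",
    "tendon_stress",
    "elastic_energy",
]

MUSCLES = ("FDS", "FDP", "ED")
FINGERS = ("index", "middle", "ring", "little")
JOINTS = ("MCP", "PIP", "DIP")

#: Joints crossed by each muscle, proximal to distal.
CROSSINGS = {
    "FDS": ("MCP", "PIP"),
    "FDP": ("MCP", "PIP", "DIP"),
    "ED": ("MCP", "PIP", "DIP"),
}


class ConfigurationError(ValueError):
    """Invalid model configuration (non-positive stiffness, bad joint class...)."""


class SolverError(RuntimeError):
    """Equilibrium iteration failed to converge."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class ParameterSet:
    """The four calibrated material parameters (N–mm–MPa units)."""

    tendon_modulus: float      # MPa
    ligament_modulus: float    # MPa
    ip_spring_stiffness: float   # N/mm, each of three springs at PIP and DIP
    mcp_spring_stiffness: float  # N/mm, each of three springs at MCP

    def __post_init__(self) -> None:
        for name in (
            "tendon_modulus",
            "ligament_modulus",
            "ip_spring_stiffness",
            "mcp_spring_stiffness",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.tendon_modulus,
                self.ligament_modulus,
                self.ip_spring_stiffness,
                self.mcp_spring_stiffness,
            ]
        )

    @staticmethod
    def from_array(values) -> "ParameterSet":
        t, l, ip, mcp = (float(v) for v in values)
        return ParameterSet(t, l, ip, mcp)

    @staticmethod
    def names() -> tuple[str, ...]:
        return (
            "tendon_modulus",
            "ligament_modulus",
            "ip_spring_stiffness",
            "mcp_spring_stiffness",
        )


#: Preset material values prior to calibration (moduli from cadaver
#: literature; spring stiffnesses at their determined magnitudes since no
#: preset is reported for them).
PRESET_PARAMETERS = ParameterSet(
    tendon_modulus=125.31,
    ligament_modulus=114.03,
    ip_spring_stiffness=1.0,
    mcp_spring_stiffness=2.0,
)

#: Values determined in the source experiment (tendon 68 MPa, ligament
#: 20 MPa, IP springs 1 N/mm = 1000 N/m, MCP springs 2 N/mm = 2000 N/m).
DETERMINED_PARAMETERS = ParameterSet(
    tendon_modulus=68.0,
    ligament_modulus=20.0,
    ip_spring_stiffness=1.0,
    mcp_spring_stiffness=2.0,
)


@dataclass(frozen=True)
class JointSpec:
    """One torsional joint: class, spring geometry and admissible angle range.

    ``angle`` is the reference (rest) angle, 0 = straight; flexion positive.
    """

    joint_class: str
    spring_lever_arm: float = 5.0            # mm, joint centre to spring line
    angle: float = 0.0                       # rad, rest angle
    angle_range: tuple[float, float] = (0.0, math.pi / 2)

    def __post_init__(self) -> None:
        if self.joint_class not in JOINTS:
            raise ConfigurationError(f"unknown joint class {self.joint_class!r}")
        if not self.spring_lever_arm > 0:
            raise ConfigurationError("spring_lever_arm must be positive")
        lo, hi = self.angle_range
        if not lo <= self.angle <= hi:
            raise ConfigurationError("rest angle outside angle_range")


@dataclass(frozen=True)
class TendonSlip:
    """One muscle's tendon path over one finger.

    ``moment_arms`` maps crossed joint class -> signed arm (mm); flexion-
    producing arms positive, so extensor arms are negative.  The slip's
    series elasticity combines the tendon (area/length from the MTJ to the
    insertion) and the retaining ligament (pulleys/retinaculum) that
    constrains its path.
    """

    muscle_id: str
    finger_id: str
    moment_arms: dict[str, float]
    cross_section_area: float   # mm², tendon
    free_length: float          # mm, tendon
    ligament_area: float = 10.0   # mm²
    ligament_length: float = 20.0  # mm
    #: fractional growth of the moment arm per radian of flexion
    #: (bowstringing between pulleys); instantaneous arm r_j·(1 + γ·θ_j),
    #: excursion r_j·(θ_j + γ·θ_j²/2).  0 = constant-arm geometry.
    arm_growth: float = 0.0

    def __post_init__(self) -> None:
        if self.muscle_id not in MUSCLES:
            raise ConfigurationError(f"unknown muscle {self.muscle_id!r}")
        if self.finger_id not in FINGERS:
            raise ConfigurationError(f"unknown finger {self.finger_id!r}")
        expected = CROSSINGS[self.muscle_id]
        if set(self.moment_arms) != set(expected):
            raise ConfigurationError(
                f"{self.muscle_id} must cross exactly {expected}, got {tuple(self.moment_arms)}"
            )
        sign = -1.0 if self.muscle_id == "ED" else 1.0
        for joint, arm in self.moment_arms.items():
            if sign * arm <= 0:
                raise ConfigurationError(
                    f"{self.muscle_id} arm at {joint} must be {'negative' if sign < 0 else 'positive'}"
                )
        for name in ("cross_section_area", "free_length", "ligament_area", "ligament_length"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.arm_growth < 0:
            raise ConfigurationError("arm_growth cannot be negative")


@dataclass
class Muscle:
    """A rigid-body muscle whose MTJ displacement loads all four slips."""

    muscle_id: str
    slips: dict[str, TendonSlip]
    applied_displacement: float = 0.0  # mm, shortening positive

    def __post_init__(self) -> None:
        if set(self.slips) != set(FINGERS):
            raise ConfigurationError(f"{self.muscle_id} needs one slip per finger")
        for finger, slip in self.slips.items():
            if slip.muscle_id != self.muscle_id or slip.finger_id != finger:
                raise ConfigurationError("slip ids inconsistent with muscle map")


@dataclass(frozen=True)
class FingerSpec:
    """One finger chain: phalanx lengths (proximal, middle, distal) and joints."""

    finger_id: str
    phalanx_lengths: tuple[float, float, float]  # mm
    joints: dict[str, JointSpec]

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.phalanx_lengths):
            raise ConfigurationError("phalanx lengths must be positive")
        if tuple(self.joints) != JOINTS:
            raise ConfigurationError("finger needs MCP, PIP, DIP joints in order")


@dataclass
class HandModel:
    """Four finger chains, three muscles, one parameter set.

    ``contact_penalty`` is the plate penalty stiffness (N/mm);
    ``contact_offset`` the lever (mm) of the plate reaction about the DIP
    joint — 0 places the reaction at the pad overlying the DIP, letting the
    distal phalanx curl past the plate edge as observed under resistance.
    """

    fingers: dict[str, FingerSpec]
    muscles: dict[str, Muscle]
    parameters: ParameterSet
    contact_penalty: float = 1000.0  # N/mm
    contact_offset: float = 0.0      # mm
    #: height (mm) the pad contact point must rise before meeting the plate:
    #: the plate is set against the belly of the flat finger, so the thinner
    #: distal pad presses only after some PIP flexion
    plate_clearance: float = 0.0

    def __post_init__(self) -> None:
        if tuple(self.fingers) != FINGERS:
            raise ConfigurationError(f"fingers must be exactly {FINGERS}")
        if set(self.muscles) != set(MUSCLES):
            raise ConfigurationError(f"muscles must be exactly {set(MUSCLES)}")
        if not self.contact_penalty > 0:
            raise ConfigurationError("contact_penalty must be positive")

    def with_parameters(self, params: ParameterSet) -> "HandModel":
        return HandModel(
            fingers=self.fingers,
            muscles={
                m: Muscle(mus.muscle_id, dict(mus.slips), mus.applied_displacement)
                for m, mus in self.muscles.items()
            },
            parameters=params,
            contact_penalty=self.contact_penalty,
            contact_offset=self.contact_offset,
            plate_clearance=self.plate_clearance,
        )


@dataclass
class EquilibriumState:
    """One converged quasi-static state of the whole hand."""

    joint_angles: dict[str, np.ndarray]          # finger -> (θ_MCP, θ_PIP, θ_DIP) rad
    slip_tensions: dict[tuple[str, str], float]  # (muscle, finger) -> N
    muscle_forces: dict[str, float]              # muscle -> N (sum of slips)
    fingertip_forces: dict[str, float]           # finger -> N
    total_fingertip_force: float                 # N
    residual_norm: float                         # N·mm, over free unclamped joints
    clamped: dict[str, np.ndarray] = field(default_factory=dict)  # finger -> bool(3)
    load_fraction: float = 1.0

    def angles_vector(self) -> np.ndarray:
        return np.concatenate([self.joint_angles[f] for f in FINGERS])


# ---------------------------------------------------------------------------
# Elementary force laws
# ---------------------------------------------------------------------------

def torsional_stiffness_from_linear(linear_stiffness: float, lever_arm: float) -> float:
    """Small-angle torsional equivalent of three identical linear springs.

    Three springs of stiffness ``k`` at radius ``l`` resisting a rotation θ
    each stretch by ≈ l·θ, producing restoring torque 3·k·l²·θ.
    """
    if linear_stiffness < 0:
        raise ConfigurationError("spring stiffness cannot be negative")
    return 3.0 * linear_stiffness * lever_arm**2


def rotational_stiffness(joint: JointSpec, params: ParameterSet) -> float:
    """Torsional stiffness K (N·mm/rad) of a joint under the parameter set."""
    if joint.joint_class == "MCP":
        k = params.mcp_spring_stiffness
    elif joint.joint_class in ("PIP", "DIP"):
        k = params.ip_spring_stiffness
    else:  # pragma: no cover - JointSpec already validates
        raise ConfigurationError(f"unknown joint class {joint.joint_class!r}")
    return torsional_stiffness_from_linear(k, joint.spring_lever_arm)


def tendon_excursion(slip: TendonSlip, joint_angles: dict[str, float]) -> float:
    """Geometric tendon travel over the slip's crossed joints.

    E = Σ_j r_j·(θ_j + γ·θ_j²/2), the integral of the instantaneous arm
    r_j·(1 + γ·θ_j); with the default γ = 0 this is the constant-arm sum
    Σ r_j·θ_j.  Positive for a flexor reeled in by flexion, negative for
    the extensor.
    """
    g = slip.arm_growth
    return float(
        sum(
            arm * (joint_angles[j] + 0.5 * g * joint_angles[j] ** 2)
            for j, arm in slip.moment_arms.items()
        )
    )


def effective_stiffness(slip: TendonSlip, params: ParameterSet) -> float:
    """Series stiffness (N/mm) of tendon and retaining ligament.

    k_t = E_t·A_t/L_t, k_lig = E_lig·A_lig/L_lig, combined in series.
    Strictly increasing in both moduli.
    """
    if params.tendon_modulus <= 0 or params.ligament_modulus <= 0:
        raise ConfigurationError("moduli must be positive")
    k_t = params.tendon_modulus * slip.cross_section_area / slip.free_length
    k_lig = params.ligament_modulus * slip.ligament_area / slip.ligament_length
    return 1.0 / (1.0 / k_t + 1.0 / k_lig)


def slip_tension(
    slip: TendonSlip,
    applied_displacement: float,
    joint_angles: dict[str, float],
    params: ParameterSet,
) -> float:
    """Tension (N) of one slip: k_eff · max(x − E(θ), 0).

    The elastic stretch is the applied MTJ displacement (shortening
    positive) minus the excursion already absorbed by joint rotation; a
    slack tendon carries no force.
    """
    stretch = applied_displacement - tendon_excursion(slip, joint_angles)
    if stretch <= 0:
        return 0.0
    return effective_stiffness(slip, params) * stretch


def tendon_stress(force: float, area: float) -> float:
    """Nominal tendon stress σ = F/A (MPa)."""
    if area <= 0:
        raise ConfigurationError("area must be positive")
    return force / area


# ---------------------------------------------------------------------------
# Per-finger assembly
# ---------------------------------------------------------------------------

def _contact_gap_and_lever(
    finger: FingerSpec, theta: np.ndarray, contact_offset: float, clearance: float = 0.0
) -> tuple[float, np.ndarray]:
    """Penetration (mm) of the pad contact point past the plate plane, and
    its lever vector ∂g/∂θ about (MCP, PIP, DIP).

    With the proximal phalanx fixed, the pad point overlying the DIP (plus
    an optional offset along the distal phalanx) rises by
    L2·sin θ_PIP + c·sin(θ_PIP + θ_DIP); it penetrates the plate once that
    rise exceeds the plate clearance.
    """
    L2 = finger.phalanx_lengths[1]
    tp, td = float(theta[1]), float(theta[2])
    g = L2 * math.sin(tp) + contact_offset * math.sin(tp + td) - clearance
    lever = np.array(
        [
            0.0,
            L2 * math.cos(tp) + contact_offset * math.cos(tp + td),
            contact_offset * math.cos(tp + td),
        ]
    )
    return g, lever


def contact_force(
    model: HandModel, finger_id: str, joint_angles: dict[str, float] | np.ndarray
) -> float:
    """Unilateral penalty plate reaction N = k_c·max(g, 0) on one finger."""
    finger = model.fingers[finger_id]
    theta = (
        np.asarray(joint_angles, dtype=float)
        if not isinstance(joint_angles, dict)
        else np.array([joint_angles[j] for j in JOINTS])
    )
    g, _ = _contact_gap_and_lever(
        finger, theta, model.contact_offset, model.plate_clearance
    )
    return model.contact_penalty * max(g, 0.0)


class _FingerSystem:
    """Cached per-finger arrays for fast residual/energy/Jacobian evaluation."""

    def __init__(self, model: HandModel, finger_id: str, resisted: bool):
        finger = model.fingers[finger_id]
        self.finger = finger
        self.resisted = resisted
        self.contact_penalty = model.contact_penalty
        self.contact_offset = model.contact_offset
        self.plate_clearance = model.plate_clearance
        self.K = np.array(
            [rotational_stiffness(finger.joints[j], model.parameters) for j in JOINTS]
        )
        self.lo = np.array([finger.joints[j].angle_range[0] for j in JOINTS])
        self.hi = np.array([finger.joints[j].angle_range[1] for j in JOINTS])
        # moment-arm rows per muscle, aligned with JOINTS
        self.R = np.zeros((len(MUSCLES), 3))
        self.k_eff = np.zeros(len(MUSCLES))
        self.gamma = np.zeros(len(MUSCLES))
        for i, m in enumerate(MUSCLES):
            slip = model.muscles[m].slips[finger_id]
            for j, joint in enumerate(JOINTS):
                self.R[i, j] = slip.moment_arms.get(joint, 0.0)
            self.k_eff[i] = effective_stiffness(slip, model.parameters)
            self.gamma[i] = slip.arm_growth
        # resisted flexion: proximal phalanx held -> MCP angle frozen at rest
        self.free = np.array([not resisted, True, True])

    def excursions(self, theta: np.ndarray) -> np.ndarray:
        # E_m = Σ_j R0_mj (θ_j + γ_m θ_j²/2)
        return self.R @ theta + 0.5 * self.gamma * (self.R @ theta**2)

    def arms(self, theta: np.ndarray) -> np.ndarray:
        # instantaneous arms dE_m/dθ_j = R0_mj (1 + γ_m θ_j)
        return self.R * (1.0 + self.gamma[:, None] * theta[None, :])

    def tensions(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        stretch = x - self.excursions(theta)
        return self.k_eff * np.maximum(stretch, 0.0)

    def normal(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if not self.resisted:
            return 0.0, np.zeros(3)
        g, lever = _contact_gap_and_lever(
            self.finger, theta, self.contact_offset, self.plate_clearance
        )
        return self.contact_penalty * max(g, 0.0), lever

    def residual(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        F = self.tensions(theta, x)
        N, lever = self.normal(theta)
        return self.arms(theta).T @ F - self.K * theta - N * lever

    def energy(self, theta: np.ndarray, x: np.ndarray) -> float:
        stretch = np.maximum(x - self.excursions(theta), 0.0)
        U = 0.5 * float(self.k_eff @ stretch**2) + 0.5 * float(self.K @ theta**2)
        if self.resisted:
            g, _ = _contact_gap_and_lever(
                self.finger, theta, self.contact_offset, self.plate_clearance
            )
            U += 0.5 * self.contact_penalty * max(g, 0.0) ** 2
        return U

    def jacobian(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        """d(residual)/dθ, symmetric negative semidefinite."""
        stretch = x - self.excursions(theta)
        active = (stretch > 0).astype(float)
        F = self.k_eff * np.maximum(stretch, 0.0)
        A = self.arms(theta)
        J = -(A.T * (self.k_eff * active)) @ A - np.diag(self.K)
        # arm-growth curvature: d(arm_mj)/dθ_j = R0_mj γ_m
        J += np.diag((self.R * self.gamma[:, None]).T @ F)
        if self.resisted:
            g, lever = _contact_gap_and_lever(
                self.finger, theta, self.contact_offset, self.plate_clearance
            )
            if g > 0:
                J -= self.contact_penalty * np.outer(lever, lever)
                # curvature of the gap function: g'' terms
                L2 = self.finger.phalanx_lengths[1]
                c = self.contact_offset
                tp, td = float(theta[1]), float(theta[2])
                spp = -L2 * math.sin(tp) - c * math.sin(tp + td)
                spd = -c * math.sin(tp + td)
                N = self.contact_penalty * g
                H = np.array([[0.0, 0.0, 0.0], [0.0, spp, spd], [0.0, spd, spd]])
                J += N * H * -1.0
        return J


def _solve_finger(
    sys: _FingerSystem,
    x: np.ndarray,
    theta0: np.ndarray,
    tol_rel: float,
    max_iter: int,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Damped projected Newton on the residual with energy line search.

    Returns (theta, residual_norm over free unclamped joints, clamped mask).
    The potential energy is convex piecewise-smooth, so descent steps with
    backtracking converge to the unique equilibrium.
    """
    theta = np.clip(theta0, sys.lo, sys.hi).astype(float)
    theta[~sys.free] = np.clip(theta0[~sys.free], sys.lo[~sys.free], sys.hi[~sys.free])
    scale = max(
        float(np.max(np.abs(sys.R) * sys.k_eff[:, None] * np.max(np.abs(x), initial=0.0))),
        float(np.max(sys.K)) * 1.0,
        1.0,
    )
    tol = tol_rel * scale

    def free_resid(th):
        r = sys.residual(th, x)
        # joints pinned at a range bound with the residual pushing outward
        # are clamped; their reaction is the bound constraint
        clamped = (~sys.free) | ((th <= sys.lo) & (r < 0)) | ((th >= sys.hi) & (r > 0))
        r_free = r.copy()
        r_free[clamped] = 0.0
        return r, r_free, clamped

    for _ in range(max_iter):
        r, r_free, clamped = free_resid(theta)
        if np.max(np.abs(r_free)) <= tol:
            return theta, float(np.linalg.norm(r_free)), clamped
        J = sys.jacobian(theta, x)
        idx = np.where(~clamped)[0]
        # modified Newton: the energy loses convexity at large stretch when
        # arms grow with flexion, so shift the Hessian H = -J positive
        # definite to keep steps descent directions
        H = -J[np.ix_(idx, idx)]
        eigmin = float(np.min(np.linalg.eigvalsh(H))) if len(idx) else 0.0
        if eigmin < 1e-9 * scale:
            H = H + (1e-6 * scale - eigmin) * np.eye(len(idx))
        try:
            step = np.linalg.solve(H, r_free[idx])
        except np.linalg.LinAlgError:
            step = r_free[idx] / scale
        # backtracking on potential energy (gradient of U is -residual)
        U0 = sys.energy(theta, x)
        alpha = 1.0
        for _ls in range(40):
            trial = theta.copy()
            trial[idx] += alpha * step
            trial = np.clip(trial, sys.lo, sys.hi)
            if sys.energy(trial, x) <= U0 + 1e-12 * abs(U0):
                theta = trial
                break
            alpha *= 0.5
        else:
            theta[idx] += 1e-3 * r_free[idx] / scale
            theta = np.clip(theta, sys.lo, sys.hi)
    r, r_free, clamped = free_resid(theta)
    norm = float(np.linalg.norm(r_free))
    if np.max(np.abs(r_free)) > tol:
        raise SolverError(
            f"finger {sys.finger.finger_id} equilibrium did not converge "
            f"(|residual|={norm:.3e} N·mm, tol={tol:.3e})",
            residual_norm=norm,
        )
    return theta, norm, clamped


# ---------------------------------------------------------------------------
# Hand-level equilibrium
# ---------------------------------------------------------------------------

def residual_torques(
    model: HandModel,
    joint_angles: dict[str, np.ndarray],
    displacements: dict[str, float],
    mode: str = "free",
) -> dict[str, np.ndarray]:
    """Net torque (N·mm) at every free joint of every finger.

    ρ_j = Σ_slips r_{s,j}·F_s − K_j·θ_j − lever_j·N; zero at equilibrium.
    In resisted mode the MCP entry is reported as 0 (reacted by the fixed
    proximal phalanx).
    """
    resisted = mode == "resisted"
    x = np.array([displacements.get(m, 0.0) for m in MUSCLES])
    out = {}
    for f in FINGERS:
        sys = _FingerSystem(model, f, resisted)
        theta = np.asarray(joint_angles[f], dtype=float)
        r = sys.residual(theta, x)
        r[~sys.free] = 0.0
        out[f] = r
    return out


def solve_equilibrium(
    model: HandModel,
    displacements: dict[str, float],
    mode: str = "free",
    initial_angles: dict[str, np.ndarray] | None = None,
    tol_rel: float = 1e-8,
    max_iter: int = 200,
) -> EquilibriumState:
    """Quasi-static equilibrium of the hand under prescribed MTJ displacements.

    ``mode`` is ``"free"`` (all joints free, no plate) or ``"resisted"``
    (MCP frozen at its rest angle, unilateral plate contact at the pad).
    Deterministic given inputs; fingers decouple and are solved by damped
    Newton iteration.  A zero-displacement load returns the rest state
    without invoking the solver.
    """
    if mode not in ("free", "resisted"):
        raise ConfigurationError(f"unknown constraint mode {mode!r}")
    x = np.array([float(displacements.get(m, 0.0)) for m in MUSCLES])
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("displacements must be finite")
    resisted = mode == "resisted"

    rest = {
        f: np.array([model.fingers[f].joints[j].angle for j in JOINTS]) for f in FINGERS
    }
    if np.all(x == 0.0) and all(np.all(rest[f] == 0.0) for f in FINGERS):
        zero = {f: np.zeros(3) for f in FINGERS}
        return EquilibriumState(
            joint_angles=zero,
            slip_tensions={(m, f): 0.0 for m in MUSCLES for f in FINGERS},
            muscle_forces={m: 0.0 for m in MUSCLES},
            fingertip_forces={f: 0.0 for f in FINGERS},
            total_fingertip_force=0.0,
            residual_norm=0.0,
            clamped={f: np.zeros(3, dtype=bool) for f in FINGERS},
        )

    angles: dict[str, np.ndarray] = {}
    tensions: dict[tuple[str, str], float] = {}
    tip: dict[str, float] = {}
    clamped: dict[str, np.ndarray] = {}
    res_sq = 0.0
    for f in FINGERS:
        sys = _FingerSystem(model, f, resisted)
        theta0 = (
            np.asarray(initial_angles[f], dtype=float)
            if initial_angles is not None
            else rest[f].copy()
        )
        theta, rnorm, cl = _solve_finger(sys, x, theta0, tol_rel, max_iter)
        angles[f] = theta
        clamped[f] = cl & sys.free  # only range clamps are warnings
        res_sq += rnorm**2
        F = sys.tensions(theta, x)
        for i, m in enumerate(MUSCLES):
            tensions[(m, f)] = float(F[i])
        N, _ = sys.normal(theta)
        tip[f] = float(N)

    muscle_forces = {m: float(sum(tensions[(m, f)] for f in FINGERS)) for m in MUSCLES}
    total = float(sum(tip.values()))
    return EquilibriumState(
        joint_angles=angles,
        slip_tensions=tensions,
        muscle_forces=muscle_forces,
        fingertip_forces=tip,
        total_fingertip_force=total,
        residual_norm=math.sqrt(res_sq),
        clamped=clamped,
    )


def elastic_energy(
    model: HandModel, state: EquilibriumState, displacements: dict[str, float], mode: str = "free"
) -> float:
    """Total stored elastic energy (N·mm): tendon stretch + joint springs
    (+ contact penalty in resisted mode)."""
    x = np.array([displacements.get(m, 0.0) for m in MUSCLES])
    resisted = mode == "resisted"
    return float(
        sum(
            _FingerSystem(model, f, resisted).energy(
                np.asarray(state.joint_angles[f], dtype=float), x
            )
            for f in FINGERS
        )
    )
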