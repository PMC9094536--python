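"""Synthetic study generation for closed-loop parameter recovery.

The original study measured a single subject: CT-derived geometry, five MTJ
displacement protocols, and platform fingertip forces.  None of that raw
data is deposited, so this module generates the same kind of study from a
known ground truth — randomized but anthropometrically bounded finger
geometry, monotone resisted displacement protocols (plus an optional free
action with a lengthening extensor), and noisy observations simulated from
the forward model.  Refitting the parameters to these observations checks
the whole estimation pipeline.

Noise defaults are conservative guesses for the instruments involved:
0.2 N on platform force readings, 0.5 mm on ultrasound MTJ marking, and
0.05 rad on free-flexion posture angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import calibrate, predict_final_state
from .geometry import DEFAULT_GEOMETRY, JOINT_RANGES, _build
from .model import FINGERS, JOINTS, HandModel, ParameterSet
from .protocols import ActionSpec

__all__ = [
    "SyntheticStudy",
    "RecoveryReport",
    "make_geometry",
    "make_protocol",
    "simulate_observations",
    "recovery_experiment",
]

#: Relative jitter applied to lengths and arms when randomizing geometry.
_GEOMETRY_JITTER = 0.08

#: Default measurement noise (see module docstring).
DEFAULT_NOISE_SD_FORCE = 0.2        # N
DEFAULT_NOISE_SD_DISPLACEMENT = 0.5  # mm
DEFAULT_NOISE_SD_ANGLE = 0.05        # rad


def make_geometry(scale: float = 1.0, seed: int = 0) -> HandModel:
    """A randomized four-finger hand skeleton, deterministic per seed.

    Phalanx lengths and moment arms are drawn within ±8% of the package
    defaults and multiplied by ``scale`` (homogeneous: doubling the scale
    doubles every length and arm).  Finger size ordering is preserved:
    the index finger keeps the largest arms, the little finger the smallest.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    geo = {
        "phalanx_lengths": {},
        "arm_scale": {},
        "moment_arms": {
            m: dict(arms) for m, arms in DEFAULT_GEOMETRY["moment_arms"].items()
        },
        "arm_growth": dict(DEFAULT_GEOMETRY["arm_growth"]),
        "tendon_area": dict(DEFAULT_GEOMETRY["tendon_area"]),
        "tendon_length": dict(DEFAULT_GEOMETRY["tendon_length"]),
        "ligament_area": DEFAULT_GEOMETRY["ligament_area"],
        "ligament_length": DEFAULT_GEOMETRY["ligament_length"],
        "spring_lever_arm": DEFAULT_GEOMETRY["spring_lever_arm"],
        "contact_penalty": DEFAULT_GEOMETRY["contact_penalty"],
        "contact_offset": DEFAULT_GEOMETRY["contact_offset"],
        "plate_clearance": DEFAULT_GEOMETRY["plate_clearance"],
        "joint_ranges": JOINT_RANGES,
    }
    for f in FINGERS:
        jitter = 1.0 + _GEOMETRY_JITTER * rng.uniform(-1.0, 1.0, size=3)
        geo["phalanx_lengths"][f] = tuple(
            scale * L * j
            for L, j in zip(DEFAULT_GEOMETRY["phalanx_lengths"][f], jitter)
        )
    # jittered size factors, re-sorted so index >= middle >= ring >= little
    base = np.array([DEFAULT_GEOMETRY["arm_scale"][f] for f in FINGERS])
    jittered = base * (1.0 + _GEOMETRY_JITTER * rng.uniform(-1.0, 1.0, size=4))
    ordered = np.sort(jittered)[::-1]
    for f, s in zip(FINGERS, ordered):
        geo["arm_scale"][f] = float(s * scale)
    params = ParameterSet(
        tendon_modulus=68.0,
        ligament_modulus=20.0,
        ip_spring_stiffness=1.0,
        mcp_spring_stiffness=2.0,
    )
    return _build(geo, params)


def make_protocol(
    n_actions: int = 4,
    displacement_range: tuple[float, float] = (4.0, 21.0),
    seed: int = 0,
    include_free: bool = False,
    protocol: str = "random",
    n_steps: int = 50,
) -> list[ActionSpec]:
    """Resisted actions with monotonically increasing FDS/FDP endpoints.

    ``protocol="measured"`` returns the measured five-action catalog verbatim.
    Random protocols draw strictly increasing FDS endpoints over the range;
    FDP endpoints exceed FDS by a factor ~1.05–1.5 (the deep flexor travels
    farther); ED is zero under resistance.  With ``include_free`` a free
    action is prepended whose ED lengthens (negative displacement).
    """
    if protocol == "measured":
        from .protocols import action_catalog

        return action_catalog(n_steps=n_steps)
    if n_actions < 2:
        raise ValueError("need at least two actions")
    lo, hi = displacement_range
    if not (lo >= 0 and hi >= lo):
        raise ValueError("displacement_range must be ordered and nonnegative")
    rng = np.random.default_rng(seed)
    if hi > lo:
        fds = np.sort(rng.uniform(lo, hi, size=n_actions))
        while len(np.unique(fds)) < n_actions:  # pragma: no cover
            fds = np.sort(rng.uniform(lo, hi, size=n_actions))
    else:
        fds = np.full(n_actions, float(lo))
    ratio = rng.uniform(1.05, 1.5, size=n_actions)
    actions = []
    if include_free:
        actions.append(
            ActionSpec(
                action_id=0,
                displacements={"FDS": 18.0, "FDP": 22.0, "ED": -12.0},
                mode="free",
                n_steps=n_steps,
            )
        )
    for i, (xs, r) in enumerate(zip(fds, ratio), start=1):
        actions.append(
            ActionSpec(
                action_id=i,
                displacements={"FDS": float(xs), "FDP": float(xs * r), "ED": 0.0},
                mode="resisted",
                n_steps=n_steps,
            )
        )
    return actions


def simulate_observations(
    model: HandModel,
    actions: list[ActionSpec],
    noise_sd: float = DEFAULT_NOISE_SD_FORCE,
    seed: int = 0,
    noise_sd_angle: float = DEFAULT_NOISE_SD_ANGLE,
    n_sub: int = 6,
) -> list[ActionSpec]:
    """Attach simulated observations to each action.

    Resisted actions observe the final total fingertip force plus zero-mean
    Gaussian noise; free actions observe the final mean joint angles (the
    flexion pattern) plus angular noise.  Seed-reproducible; solver failures
    propagate.
    """
    rng = np.random.default_rng(seed)
    observed = []
    for a in actions:
        st = predict_final_state(model, a, n_sub=n_sub)
        if a.mode == "resisted":
            force = st.total_fingertip_force + rng.normal(0.0, noise_sd)
            observed.append(
                ActionSpec(
                    action_id=a.action_id,
                    displacements=dict(a.displacements),
                    mode=a.mode,
                    observed_fingertip_force=float(force),
                    n_steps=a.n_steps,
                )
            )
        else:
            mean = {
                j: float(
                    np.mean([st.joint_angles[f][i] for f in FINGERS])
                    + rng.normal(0.0, noise_sd_angle)
                )
                for i, j in enumerate(JOINTS)
            }
            observed.append(
                ActionSpec(
                    action_id=a.action_id,
                    displacements=dict(a.displacements),
                    mode=a.mode,
                    observed_joint_angles=mean,
                    n_steps=a.n_steps,
                )
            )
    return observed


@dataclass
class SyntheticStudy:
    """One generated study: truth, geometry seed, protocol and observations."""

    truth: ParameterSet
    geometry_seed: int
    noise_sd_force: float
    noise_sd_displacement: float
    actions: list[ActionSpec]
    observations: list[float | dict[str, float] | None]

    @staticmethod
    def generate(
        truth: ParameterSet,
        geometry_seed: int = 0,
        noise_seed: int = 0,
        noise_sd_force: float = DEFAULT_NOISE_SD_FORCE,
        noise_sd_displacement: float = DEFAULT_NOISE_SD_DISPLACEMENT,
        include_free: bool = True,
        n_actions: int = 4,
    ) -> tuple["SyntheticStudy", HandModel]:
        model = make_geometry(seed=geometry_seed).with_parameters(truth)
        actions = make_protocol(
            n_actions=n_actions, seed=geometry_seed, include_free=include_free
        )
        observed = simulate_observations(
            model, actions, noise_sd=noise_sd_force, seed=noise_seed
        )
        obs_values = [
            a.observed_fingertip_force
            if a.mode == "resisted"
            else a.observed_joint_angles
            for a in observed
        ]
        study = SyntheticStudy(
            truth=truth,
            geometry_seed=geometry_seed,
            noise_sd_force=noise_sd_force,
            noise_sd_displacement=noise_sd_displacement,
            actions=observed,
            observations=obs_values,
        )
        return study, model


@dataclass
class RecoveryReport:
    """Bias/RMSE of repeated simulate→calibrate replicates."""

    truth: ParameterSet
    noise_sd: float
    n_replicates: int
    fitted: list[ParameterSet]
    converged_fraction: float
    relative_bias: dict[str, float] = field(default_factory=dict)
    relative_rmse: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.truth.as_array()
        fits = np.array([p.as_array() for p in self.fitted])
        rel = (fits - t) / t
        self.relative_bias = {
            n: float(np.mean(rel[:, i])) for i, n in enumerate(ParameterSet.names())
        }
        self.relative_rmse = {
            n: float(np.sqrt(np.mean(rel[:, i] ** 2)))
            for i, n in enumerate(ParameterSet.names())
        }

    def to_dict(self) -> dict:
        return {
            "truth": {n: getattr(self.truth, n) for n in ParameterSet.names()},
            "noise_sd_force_N": self.noise_sd,
            "n_replicates": self.n_replicates,
            "converged_fraction": self.converged_fraction,
            "relative_bias": dict(self.relative_bias),
            "relative_rmse": dict(self.relative_rmse),
        }


def recovery_experiment(
    truth: ParameterSet,
    noise_sd: float = DEFAULT_NOISE_SD_FORCE,
    n_replicates: int = 1,
    seed: int = 0,
    geometry_seed: int | None = None,
    initial: ParameterSet | None = None,
    include_free: bool = True,
) -> RecoveryReport:
    """Repeat simulate→calibrate and report parameter bias and RMSE.

    One fixed geometry/protocol (from ``geometry_seed``, default ``seed``),
    fresh observation noise per replicate.  The free action's posture
    observation is what identifies the MCP spring stiffness — resisted
    actions carry no information about it because the proximal phalanges
    are fixed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    geometry_seed = seed if geometry_seed is None else geometry_seed
    model = make_geometry(seed=geometry_seed).with_parameters(truth)
    actions = make_protocol(
        n_actions=4, seed=geometry_seed, include_free=include_free
    )
    start = initial or ParameterSet(125.31, 114.03, 0.5, 0.5)
    # posture noise scales with force noise so noise_sd=0 is fully noiseless
    sd_angle = noise_sd * DEFAULT_NOISE_SD_ANGLE / DEFAULT_NOISE_SD_FORCE
    rng = np.random.default_rng(seed)
    fits: list[ParameterSet] = []
    converged = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        observed = simulate_observations(
            model, actions, noise_sd=noise_sd, seed=rep_seed, noise_sd_angle=sd_angle
        )
        result = calibrate(model, observed, initial=start)
        fits.append(result.fitted)
        converged += int(result.converged)
    return RecoveryReport(
        truth=truth,
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        fitted=fits,
        converged_fraction=converged / n_replicates,
    )
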