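"""The five experimental flexion protocols and derived force analyses.

Five actions drive the hand model through measured MTJ displacements:
action 1 is free flexion from straight to the relaxed posture; actions 2–5
press a rigid plate with increasing effort.  Fingertip force in the resisted
actions is the platform display plus the 0.7 N plate resistance, giving
observations of 5.7, 10.7, 15.7 and 20.7 N.  The extensor's MTJ displacement
under resistance is negligible and set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    MUSCLES,
    ConfigurationError,
    EquilibriumState,
    HandModel,
    SolverError,
    solve_equilibrium,
)

__all__ = [
    "PLATE_RESISTANCE",
    "ActionSpec",
    "Trajectory",
    "fingertip_force_from_display",
    "action_catalog",
    "run_action",
    "detect_plateau",
    "force_shares",
    "force_to_fingertip_ratios",
]

#: Average resistance (N) of the movable plate: its weight plus rail friction.
PLATE_RESISTANCE = 0.7

#: Measured MTJ displacement endpoints (mm, shortening positive).
_TABLE_DISPLACEMENTS = {
    1: {"FDS": 18.22, "FDP": 22.22, "ED": -12.54},
    2: {"FDS": 4.33, "FDP": 6.60, "ED": 0.0},
    3: {"FDS": 10.48, "FDP": 12.10, "ED": 0.0},
    4: {"FDS": 15.88, "FDP": 16.30, "ED": 0.0},
    5: {"FDS": 20.56, "FDP": 21.70, "ED": 0.0},
}

#: Platform display readings (N) for the resisted actions.
_DISPLAY_READINGS = {2: 5.0, 3: 10.0, 4: 15.0, 5: 20.0}

#: Physiological resting posture (rad) of the naturally relaxed hand — the
#: endpoint of free flexion.  The free action's observed "flexion pattern"
#: is quantified as these mean joint angles (MCP ≈ 40°, PIP ≈ 40°,
#: DIP ≈ 20°, standard clinical values for the hand at rest).
REST_POSTURE = {"MCP": 0.70, "PIP": 0.70, "DIP": 0.35}


def fingertip_force_from_display(display_reading: float) -> float:
    """Fingertip force = platform display + plate resistance (N)."""
    return display_reading + PLATE_RESISTANCE


@dataclass(frozen=True)
class ActionSpec:
    """One flexion protocol: displacement endpoints, mode and observation."""

    action_id: int
    displacements: dict[str, float]          # mm per muscle
    mode: str                                # "free" | "resisted"
    observed_fingertip_force: float | None = None  # N
    display_reading: float | None = None     # N
    observed_joint_angles: dict[str, float] | None = None  # rad, mean per joint
    n_steps: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("free", "resisted"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if set(self.displacements) - set(MUSCLES):
            raise ConfigurationError("displacements must key FDS/FDP/ED")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Equilibrium states along a uniformly ramped displacement load."""

    action_id: int
    load_fractions: np.ndarray          # strictly increasing, ends at 1
    states: list[EquilibriumState]
    mode: str = "free"

    def final(self) -> EquilibriumState:
        return self.states[-1]

    def muscle_force_series(self, muscle_id: str) -> np.ndarray:
        return np.array([s.muscle_forces[muscle_id] for s in self.states])

    def fingertip_force_series(self) -> np.ndarray:
        return np.array([s.total_fingertip_force for s in self.states])


def action_catalog(n_steps: int = 50, include_posture: bool = False) -> list[ActionSpec]:
    """The five measured actions with displacement endpoints and observed
    fingertip forces baked in.

    With ``include_posture`` the free action additionally carries the
    resting flexion pattern (:data:`REST_POSTURE`) as a posture observation,
    which calibration can use alongside the four force observations — the
    experiment's knowns are "fingertip force or flexion pattern".
    """
    catalog = []
    for aid in range(1, 6):
        if aid == 1:
            catalog.append(
                ActionSpec(
                    action_id=1,
                    displacements=dict(_TABLE_DISPLACEMENTS[1]),
                    mode="free",
                    observed_joint_angles=dict(REST_POSTURE) if include_posture else None,
                    n_steps=n_steps,
                )
            )
        else:
            display = _DISPLAY_READINGS[aid]
            catalog.append(
                ActionSpec(
                    action_id=aid,
                    displacements=dict(_TABLE_DISPLACEMENTS[aid]),
                    mode="resisted",
                    observed_fingertip_force=fingertip_force_from_display(display),
                    display_reading=display,
                    n_steps=n_steps,
                )
            )
    return catalog


def run_action(model: HandModel, action: ActionSpec) -> Trajectory:
    """Ramp the action's displacements linearly over ``n_steps`` equilibria.

    Each step is warm-started from the previous state.  "Time" in the
    experiment maps to load fraction: displacement loads were applied
    uniformly, so the ramp parameter is the natural clock.
    """
    fractions = np.linspace(0.0, 1.0, action.n_steps + 1)
    endpoint = {m: action.displacements.get(m, 0.0) for m in MUSCLES}
    states: list[EquilibriumState] = []
    prev_angles = None
    for i, lam in enumerate(fractions):
        x = {m: lam * endpoint[m] for m in MUSCLES}
        try:
            state = solve_equilibrium(
                model, x, mode=action.mode, initial_angles=prev_angles
            )
        except SolverError as exc:
            raise SolverError(
                f"action {action.action_id} failed at step {i} "
                f"(load fraction {lam:.3f}): {exc}",
                residual_norm=exc.residual_norm,
            ) from exc
        state.load_fraction = float(lam)
        states.append(state)
        prev_angles = state.joint_angles
    return Trajectory(
        action_id=action.action_id,
        load_fractions=fractions,
        states=states,
        mode=action.mode,
    )


def detect_plateau(
    force_series, slope_threshold: float = 0.1, min_width: int | None = None
) -> list[tuple[int, int]]:
    """Maximal sample intervals where the force barely grows.

    A step's slope is the difference between consecutive samples.  Runs of
    steps whose |slope| is at most ``slope_threshold`` times the peak |slope|
    form plateaus; an interval ``(i, j)`` spans samples ``i..j`` inclusive
    and must cover at least ``min_width`` samples (default: 10% of the
    series).  A constant series is one full-length plateau; a strictly
    uniform ramp has none.
    """
    y = np.asarray(force_series, dtype=float)
    if min_width is None:
        min_width = max(2, int(round(0.1 * len(y))))
    if len(y) < max(min_width, 2):
        raise ValueError("series shorter than min_width")
    slopes = np.abs(np.diff(y))
    peak = float(np.max(slopes))
    low = slopes <= slope_threshold * peak
    if peak == 0.0:
        return [(0, len(y) - 1)]
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if (j - i + 2) >= min_width:  # run of m steps spans m+1 samples
                intervals.append((i, j + 1))
            i = j + 1
        i += 1
    return intervals


def force_shares(muscle_forces: dict[str, float]) -> dict[str, float]:
    """FDS and FDP percentages of the total flexor force (sum to 100)."""
    fds, fdp = muscle_forces["FDS"], muscle_forces["FDP"]
    total = fds + fdp
    if total <= 0:
        raise ValueError("flexor shares undefined: FDS + FDP must be positive")
    return {"FDS": 100.0 * fds / total, "FDP": 100.0 * fdp / total}


def force_to_fingertip_ratios(trajectories: list[Trajectory]) -> dict[str, float]:
    """Mean over resisted actions of final muscle force / final total
    fingertip force, for FDS and FDP."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ratios = {m: [] for m in ("FDS", "FDP")}
    for traj in trajectories:
        final = traj.final()
        tip = final.total_fingertip_force
        if tip <= 0:
            raise ValueError(
                f"action {traj.action_id}: zero fingertip force, ratio undefined"
            )
        for m in ratios:
            ratios[m].append(final.muscle_forces[m] / tip)
    return {m: float(np.mean(v)) for m, v in ratios.items()}
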