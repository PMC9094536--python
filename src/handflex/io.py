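"""Serialization of trajectories, states and calibration reports.

Trajectories go to CSV (one row per load step), full states and calibration
results to JSON, and calibration results additionally to a human-readable
text report.  Column meanings are documented in the packaged
``data/schema.md``.
"""

from __future__ import annotations

import json

import pandas as pd

from .calibration import CalibrationResult
from .model import FINGERS, JOINTS, MUSCLES, EquilibriumState, ParameterSet
from .protocols import Trajectory

__all__ = [
    "trajectory_to_frame",
    "trajectory_to_csv",
    "state_to_dict",
    "state_to_json",
    "calibration_to_json",
    "calibration_report_text",
]


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """One row per load step: angles, muscle forces, fingertip forces."""
    rows = []
    for i, state in enumerate(traj.states):
        row: dict[str, float] = {
            "step": i,
            "load_fraction": float(traj.load_fractions[i]),
        }
        for f in FINGERS:
            for j_idx, j in enumerate(JOINTS):
                row[f"angle_{f}_{j}"] = float(state.joint_angles[f][j_idx])
        for m in MUSCLES:
            row[f"force_{m}"] = float(state.muscle_forces[m])
        for f in FINGERS:
            row[f"tip_{f}"] = float(state.fingertip_forces[f])
        row["tip_total"] = float(state.total_fingertip_force)
        row["residual_norm"] = float(state.residual_norm)
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_to_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def state_to_dict(state: EquilibriumState) -> dict:
    return {
        "joint_angles_rad": {f: list(map(float, state.joint_angles[f])) for f in FINGERS},
        "slip_tensions_N": {
            f"{m}_{f}": float(state.slip_tensions[(m, f)]) for m in MUSCLES for f in FINGERS
        },
        "muscle_forces_N": {m: float(state.muscle_forces[m]) for m in MUSCLES},
        "fingertip_forces_N": {f: float(state.fingertip_forces[f]) for f in FINGERS},
        "total_fingertip_force_N": float(state.total_fingertip_force),
        "residual_norm_Nmm": float(state.residual_norm),
        "load_fraction": float(state.load_fraction),
        "clamped_joints": {
            f: [JOINTS[i] for i, c in enumerate(state.clamped.get(f, [])) if c]
            for f in FINGERS
        },
    }


def state_to_json(state: EquilibriumState, path) -> None:
    with open(path, "w") as fh:
        json.dump(state_to_dict(state), fh, indent=2)


def calibration_to_json(result: CalibrationResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def calibration_report_text(result: CalibrationResult) -> str:
    """Plain-text report mirroring the layout of the study's result tables:
    observed vs predicted plate reactions, the error envelope, and the
    determined material values."""
    lines = []
    lines.append("Calibration of hand material parameters (units N-mm-MPa)")
    lines.append("")
    lines.append("Fingertip forces vs model plate reactions (N)")
    lines.append(f"{'action':>8} {'observed':>10} {'predicted':>10} {'error %':>9}")
    for aid in sorted(result.observed):
        lines.append(
            f"{aid:>8} {result.observed[aid]:>10.2f} "
            f"{result.predicted_reactions[aid]:>10.2f} "
            f"{result.percent_errors[aid]:>9.2f}"
        )
    lines.append(
        f"error range: {result.min_percent_error:.2f}% .. {result.max_percent_error:.2f}%"
    )
    lines.append("")
    lines.append("Determined material parameters")
    unit = {
        "tendon_modulus": "MPa",
        "ligament_modulus": "MPa",
        "ip_spring_stiffness": "N/mm",
        "mcp_spring_stiffness": "N/mm",
    }
    for n in ParameterSet.names():
        flag = "  (at bound)" if result.bounds_hit.get(n) else ""
        lines.append(f"  {n:<22} {getattr(result.fitted, n):>8.3f} {unit[n]}{flag}")
    if result.ligament_weakly_identified:
        lines.append("  note: ligament modulus weakly identified (flat profile)")
    if not result.mcp_identified:
        lines.append(
            "  note: MCP spring stiffness not identified by resisted actions "
            "(proximal phalanges fixed); value reflects its prior"
        )
    lines.append("")
    lines.append(
        f"converged: {result.converged}  evaluations: {result.n_evaluations}  "
        f"cost: {result.cost:.4g} (initial {result.initial_cost:.4g})"
    )
    return "\n".join(lines) + "\n"
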