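"""Default hand geometry and YAML configuration IO.

The source experiment's subject-specific CT geometry is not available, so
the package ships an anthropometrically plausible four-finger geometry:
phalanx lengths from standard hand-anthropometry tables and flexor/extensor
moment arms in the range of published tendon-excursion measurements
(flexor arms ~10–12 mm at MCP, 6–8 mm at PIP, ~5 mm at DIP; extensor arms
about −10/−6/−4 mm, sized so the extensor excursion at the rest posture
matches its measured passive MTJ displacement).  Everything here is configurable and calibratable.
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources

import yaml

from .model import (
    FINGERS,
    JOINTS,
    MUSCLES,
    ConfigurationError,
    FingerSpec,
    HandModel,
    JointSpec,
    Muscle,
    ParameterSet,
    TendonSlip,
    PRESET_PARAMETERS,
)

__all__ = [
    "DEFAULT_GEOMETRY",
    "default_hand",
    "hand_from_config",
    "hand_to_config",
    "load_hand",
    "save_hand",
    "config_digest",
]

#: Joint ranges (rad): straight (0) to full physiological flexion.
JOINT_RANGES = {
    "MCP": (0.0, math.radians(90.0)),
    "PIP": (0.0, math.radians(100.0)),
    "DIP": (0.0, math.radians(70.0)),
}

#: Per-finger phalanx lengths (proximal, middle, distal; mm) and an overall
#: size factor applied to moment arms.  Index carries the largest arms.
DEFAULT_GEOMETRY = {
    "phalanx_lengths": {
        "index": (45.0, 25.0, 22.0),
        "middle": (50.0, 30.0, 24.0),
        "ring": (46.0, 28.0, 23.0),
        "little": (38.0, 20.0, 20.0),
    },
    "arm_scale": {"index": 1.00, "middle": 0.98, "ring": 0.92, "little": 0.84},
    # signed moment arms (mm) for the index finger; other fingers scaled
    "moment_arms": {
        "FDS": {"MCP": 11.5, "PIP": 7.0},
        "FDP": {"MCP": 10.5, "PIP": 6.5, "DIP": 4.8},
        "ED": {"MCP": -10.5, "PIP": -6.0, "DIP": -4.0},
    },
    # flexor arms grow with flexion (bowstringing between pulleys); the deep
    # flexor, spanning all three joints, gains the most; the extensor hugs
    # the joint and keeps a constant arm
    "arm_growth": {"FDS": 0.25, "FDP": 0.40, "ED": 0.0},
    # tendon cross-sections (mm²) and free lengths (mm) per muscle; the
    # superficial flexor inserts on the middle phalanx, so its free tendon is
    # shorter and its transmission stiffer than the deep flexor's
    "tendon_area": {"FDS": 13.0, "FDP": 12.0, "ED": 8.0},
    "tendon_length": {"FDS": 230.0, "FDP": 270.0, "ED": 260.0},
    # series ligament (pulley/retinaculum) path: the deep flexor threads the
    # full fibro-osseous sheath to the distal phalanx, the superficial flexor
    # only its proximal part, the extensor mainly the retinaculum
    "ligament_area": 10.0,
    "ligament_length": {"FDS": 15.0, "FDP": 30.0, "ED": 20.0},
    # joint spring lever radius scales with joint size: MCP > PIP > DIP,
    # making the DIP torsionally the most mobile joint
    "spring_lever_arm": {"MCP": 6.0, "PIP": 5.0, "DIP": 3.5},
    "contact_penalty": 1000.0,
    "contact_offset": 0.0,
    "plate_clearance": 0.0,
}


def _build(geometry: dict, parameters: ParameterSet) -> HandModel:
    fingers = {}
    levers = geometry["spring_lever_arm"]
    if not isinstance(levers, dict):
        levers = {j: levers for j in JOINTS}
    lig_len = geometry["ligament_length"]
    if not isinstance(lig_len, dict):
        lig_len = {m: lig_len for m in MUSCLES}
    for f in FINGERS:
        joints = {
            j: JointSpec(
                joint_class=j,
                spring_lever_arm=float(levers[j]),
                angle=0.0,
                angle_range=tuple(geometry.get("joint_ranges", JOINT_RANGES)[j]),
            )
            for j in JOINTS
        }
        fingers[f] = FingerSpec(
            finger_id=f,
            phalanx_lengths=tuple(float(v) for v in geometry["phalanx_lengths"][f]),
            joints=joints,
        )
    muscles = {}
    for m in MUSCLES:
        slips = {}
        for f in FINGERS:
            s = float(geometry["arm_scale"][f])
            arms = {j: float(a) * s for j, a in geometry["moment_arms"][m].items()}
            slips[f] = TendonSlip(
                muscle_id=m,
                finger_id=f,
                moment_arms=arms,
                cross_section_area=float(geometry["tendon_area"][m]),
                free_length=float(geometry["tendon_length"][m]),
                ligament_area=float(geometry["ligament_area"]),
                ligament_length=float(lig_len[m]),
                arm_growth=float(geometry.get("arm_growth", {}).get(m, 0.0)),
            )
        muscles[m] = Muscle(muscle_id=m, slips=slips)
    return HandModel(
        fingers=fingers,
        muscles=muscles,
        parameters=parameters,
        contact_penalty=float(geometry["contact_penalty"]),
        contact_offset=float(geometry["contact_offset"]),
        plate_clearance=float(geometry.get("plate_clearance", 6.0)),
    )


def default_hand(parameters: ParameterSet | None = None) -> HandModel:
    """The package's default four-finger hand with preset material values."""
    return _build(DEFAULT_GEOMETRY, parameters or PRESET_PARAMETERS)


# ---------------------------------------------------------------------------
# YAML config round trip
# ---------------------------------------------------------------------------

def hand_to_config(model: HandModel) -> dict:
    """Serialize a model to a plain dict (units N–mm–MPa)."""
    any_slip = next(iter(model.muscles["FDS"].slips.values()))
    cfg = {
        "units": "N-mm-MPa",
        "parameters": {
            "tendon_modulus": model.parameters.tendon_modulus,
            "ligament_modulus": model.parameters.ligament_modulus,
            "ip_spring_stiffness": model.parameters.ip_spring_stiffness,
            "mcp_spring_stiffness": model.parameters.mcp_spring_stiffness,
        },
        "contact_penalty": model.contact_penalty,
        "contact_offset": model.contact_offset,
        "plate_clearance": model.plate_clearance,
        "fingers": {},
        "muscles": {},
    }
    for f, spec in model.fingers.items():
        cfg["fingers"][f] = {
            "phalanx_lengths": list(spec.phalanx_lengths),
            "joints": {
                j: {
                    "spring_lever_arm": js.spring_lever_arm,
                    "angle_range": list(js.angle_range),
                }
                for j, js in spec.joints.items()
            },
        }
    for m, mus in model.muscles.items():
        cfg["muscles"][m] = {
            f: {
                "moment_arms": dict(slip.moment_arms),
                "cross_section_area": slip.cross_section_area,
                "free_length": slip.free_length,
                "ligament_area": slip.ligament_area,
                "ligament_length": slip.ligament_length,
                "arm_growth": slip.arm_growth,
            }
            for f, slip in mus.slips.items()
        }
    return cfg


def hand_from_config(cfg: dict) -> HandModel:
    """Build a model from a config dict (inverse of :func:`hand_to_config`)."""
    try:
        p = cfg["parameters"]
        params = ParameterSet(
            float(p["tendon_modulus"]),
            float(p["ligament_modulus"]),
            float(p["ip_spring_stiffness"]),
            float(p["mcp_spring_stiffness"]),
        )
        fingers = {}
        for f in FINGERS:
            fc = cfg["fingers"][f]
            joints = {
                j: JointSpec(
                    joint_class=j,
                    spring_lever_arm=float(fc["joints"][j]["spring_lever_arm"]),
                    angle_range=tuple(float(v) for v in fc["joints"][j]["angle_range"]),
                )
                for j in JOINTS
            }
            fingers[f] = FingerSpec(
                finger_id=f,
                phalanx_lengths=tuple(float(v) for v in fc["phalanx_lengths"]),
                joints=joints,
            )
        muscles = {}
        for m in MUSCLES:
            slips = {
                f: TendonSlip(
                    muscle_id=m,
                    finger_id=f,
                    moment_arms={j: float(a) for j, a in sc["moment_arms"].items()},
                    cross_section_area=float(sc["cross_section_area"]),
                    free_length=float(sc["free_length"]),
                    ligament_area=float(sc["ligament_area"]),
                    ligament_length=float(sc["ligament_length"]),
                    arm_growth=float(sc.get("arm_growth", 0.0)),
                )
                for f, sc in cfg["muscles"][m].items()
            }
            muscles[m] = Muscle(muscle_id=m, slips=slips)
        return HandModel(
            fingers=fingers,
            muscles=muscles,
            parameters=params,
            contact_penalty=float(cfg.get("contact_penalty", 1000.0)),
            contact_offset=float(cfg.get("contact_offset", 0.0)),
            plate_clearance=float(cfg.get("plate_clearance", 6.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid hand config: {exc}") from exc


def save_hand(model: HandModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(hand_to_config(model), fh, sort_keys=True)


def load_hand(path) -> HandModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return hand_from_config(cfg)


def config_digest(model: HandModel) -> str:
    """Stable short hash of the full model configuration, for run logs."""
    text = yaml.safe_dump(hand_to_config(model), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def packaged_default_config() -> dict:
    """The shipped default_hand.yaml as a dict."""
    with resources.files("handflex.data").joinpath("default_hand.yaml").open() as fh:
        return yaml.safe_load(fh)
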