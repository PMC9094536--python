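import numpy as np
import pytest
from hypothesis import settings

import handflex as hf
from handflex.model import (
    FINGERS,
    JOINTS,
    FingerSpec,
    HandModel,
    JointSpec,
    Muscle,
    ParameterSet,
    TendonSlip,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    """Preset-parameter hand (material values prior to calibration)."""
    return hf.default_hand()


@pytest.fixture(scope="session")
def catalog():
    """The five measured actions, free action carrying the rest posture."""
    return hf.action_catalog(include_posture=True)


@pytest.fixture(scope="session")
def calibration_result(default_model, catalog):
    """The full calibration against the four resisted fingertip forces plus
    the free-flexion posture; computed once per session."""
    return hf.calibrate(default_model, catalog)


@pytest.fixture(scope="session")
def calibrated_model(default_model, calibration_result):
    return default_model.with_parameters(calibration_result.fitted)


@pytest.fixture(scope="session")
def calibrated_trajectories(calibrated_model, catalog):
    """Trajectories of all five actions under the calibrated model."""
    return {a.action_id: hf.run_action(calibrated_model, a) for a in catalog}


def make_single_flexor_hand(
    r: float,
    k_linear: float,
    lever: float,
    tendon_area: float = 10.0,
    tendon_length: float = 100.0,
    tendon_modulus: float = 50.0,
) -> HandModel:
    """A hand reduced to one effective degree of freedom: the FDS acts on the
    MCP with arm ``r``; every other coupling is made negligibly small so the
    index-finger MCP behaves as the textbook single-joint system.

    The huge ligament modulus makes k_eff equal the bare tendon stiffness.
    """
    params = ParameterSet(
        tendon_modulus=tendon_modulus,
        ligament_modulus=1e12,
        ip_spring_stiffness=k_linear,
        mcp_spring_stiffness=k_linear,
    )
    eps_arm = 1e-9
    fingers = {
        f: FingerSpec(
            finger_id=f,
            phalanx_lengths=(45.0, 25.0, 22.0),
            joints={
                j: JointSpec(joint_class=j, spring_lever_arm=lever, angle_range=(0.0, np.pi))
                for j in JOINTS
            },
        )
        for f in FINGERS
    }

    def slip(m, f, arms, area):
        return TendonSlip(
            muscle_id=m,
            finger_id=f,
            moment_arms=arms,
            cross_section_area=area,
            free_length=tendon_length,
            ligament_area=10.0,
            ligament_length=1.0,
        )

    tiny = 1e-9  # negligible cross-section: force scale ~1e-11 N
    muscles = {
        "FDS": Muscle(
            "FDS",
            {
                f: slip(
                    "FDS",
                    f,
                    {"MCP": r if f == "index" else eps_arm, "PIP": eps_arm},
                    tendon_area if f == "index" else tiny,
                )
                for f in FINGERS
            },
        ),
        "FDP": Muscle(
            "FDP",
            {
                f: slip("FDP", f, {"MCP": eps_arm, "PIP": eps_arm, "DIP": eps_arm}, tiny)
                for f in FINGERS
            },
        ),
        "ED": Muscle(
            "ED",
            {
                f: slip("ED", f, {"MCP": -eps_arm, "PIP": -eps_arm, "DIP": -eps_arm}, tiny)
                for f in FINGERS
            },
        ),
    }
    return HandModel(fingers=fingers, muscles=muscles, parameters=params)
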