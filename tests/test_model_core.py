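"""Unit and property tests for the core mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import handflex as hf
from handflex.model import (
    FINGERS,
    JOINTS,
    MUSCLES,
    ConfigurationError,
    JointSpec,
    ParameterSet,
    TendonSlip,
    contact_force,
    effective_stiffness,
    elastic_energy,
    residual_torques,
    rotational_stiffness,
    slip_tension,
    solve_equilibrium,
    tendon_excursion,
    tendon_stress,
    torsional_stiffness_from_linear,
)
from .conftest import make_single_flexor_hand


def fds_slip(arms, **kw):
    kw.setdefault("cross_section_area", 10.0)
    kw.setdefault("free_length", 250.0)
    return TendonSlip("FDS", "index", arms, **kw)


def fdp_slip(arms, **kw):
    kw.setdefault("cross_section_area", 10.0)
    kw.setdefault("free_length", 250.0)
    return TendonSlip("FDP", "index", arms, **kw)


def ed_slip(arms, **kw):
    kw.setdefault("cross_section_area", 10.0)
    kw.setdefault("free_length", 250.0)
    return TendonSlip("ED", "index", arms, **kw)


class TestRotationalStiffness:
    @pytest.mark.parametrize(
        "k, lever, expected",
        [(1.0, 5.0, 75.0), (2.0, 5.0, 150.0), (0.0, 5.0, 0.0), (1.0, 3.5, 36.75)],
    )
    def test_three_spring_equivalent(self, k, lever, expected):
        assert torsional_stiffness_from_linear(k, lever) == pytest.approx(expected)

    def test_dispatch_by_joint_class(self):
        params = ParameterSet(68.0, 20.0, 1.0, 2.0)
        assert rotational_stiffness(
            JointSpec("PIP", spring_lever_arm=5.0), params
        ) == pytest.approx(75.0)
        assert rotational_stiffness(
            JointSpec("DIP", spring_lever_arm=5.0), params
        ) == pytest.approx(75.0)
        assert rotational_stiffness(
            JointSpec("MCP", spring_lever_arm=5.0), params
        ) == pytest.approx(150.0)

    def test_unknown_joint_class_rejected(self):
        with pytest.raises(ConfigurationError):
            JointSpec("CMC")


class TestTendonExcursion:
    def test_straight_posture_is_zero(self):
        slip = fdp_slip({"MCP": 10.0, "PIP": 7.0, "DIP": 5.0})
        assert tendon_excursion(slip, {"MCP": 0.0, "PIP": 0.0, "DIP": 0.0}) == 0.0

    def test_linear_sum_of_arm_angle_products(self):
        slip = fdp_slip({"MCP": 10.0, "PIP": 7.0, "DIP": 5.0})
        E = tendon_excursion(slip, {"MCP": 0.5, "PIP": 0.6, "DIP": 0.4})
        assert E == pytest.approx(11.2, rel=1e-12)

    def test_extensor_sign_convention(self):
        slip = ed_slip({"MCP": -8.0, "PIP": -5.0, "DIP": -3.0})
        E = tendon_excursion(slip, {"MCP": 0.5, "PIP": 0.6, "DIP": 0.4})
        assert E == pytest.approx(-8.2, rel=1e-12)

    def test_arm_growth_adds_quadratic_term(self):
        # with growth γ the excursion is Σ r(θ + γθ²/2)
        slip = fdp_slip({"MCP": 10.0, "PIP": 7.0, "DIP": 5.0}, arm_growth=0.4)
        E = tendon_excursion(slip, {"MCP": 0.5, "PIP": 0.0, "DIP": 0.0})
        assert E == pytest.approx(10.0 * (0.5 + 0.2 * 0.25), rel=1e-12)


class TestEffectiveStiffness:
    def test_series_combination_oracle(self):
        # hand arithmetic: k_t = 68·10/250 = 2.72, k_lig = 20·10/20 = 10,
        # series: 1/(1/2.72 + 1/10) = 2.1384...
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0}, ligament_area=10.0, ligament_length=20.0)
        params = ParameterSet(68.0, 20.0, 1.0, 2.0)
        assert effective_stiffness(slip, params) == pytest.approx(2.138364779, rel=1e-8)

    def test_rigid_ligament_limit_is_bare_tendon(self):
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0})
        params = ParameterSet(68.0, 1e12, 1.0, 2.0)
        assert effective_stiffness(slip, params) == pytest.approx(2.72, rel=1e-9)

    @given(scale=st.floats(1.01, 10.0))
    def test_strictly_increasing_in_both_moduli(self, scale):
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0})
        base = ParameterSet(68.0, 20.0, 1.0, 2.0)
        k0 = effective_stiffness(slip, base)
        assert effective_stiffness(slip, ParameterSet(68.0 * scale, 20.0, 1.0, 2.0)) > k0
        assert effective_stiffness(slip, ParameterSet(68.0, 20.0 * scale, 1.0, 2.0)) > k0


class TestSlipTension:
    def test_unstretched_and_slack(self):
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0})
        params = ParameterSet(68.0, 20.0, 1.0, 2.0)
        angles = {"MCP": 0.5, "PIP": 0.6}
        E = tendon_excursion(slip, angles)
        assert slip_tension(slip, E, angles, params) == 0.0
        assert slip_tension(slip, E - 1.0, angles, params) == 0.0

    def test_tension_is_stiffness_times_stretch(self):
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0})
        params = ParameterSet(68.0, 20.0, 1.0, 2.0)
        angles = {"MCP": 0.5, "PIP": 0.6}
        E = tendon_excursion(slip, angles)
        F = slip_tension(slip, E + 2.0, angles, params)
        assert F == pytest.approx(2.0 * 2.138364779, rel=1e-8)

    @given(
        x=st.floats(-20, 30),
        th1=st.floats(0, 1.5),
        th2=st.floats(0, 1.5),
    )
    def test_slack_complementarity(self, x, th1, th2):
        """tension·min(x−E, 0) = 0 exactly: a slack tendon carries no force."""
        slip = fds_slip({"MCP": 10.0, "PIP": 7.0})
        params = ParameterSet(68.0, 20.0, 1.0, 2.0)
        angles = {"MCP": th1, "PIP": th2}
        E = tendon_excursion(slip, angles)
        F = slip_tension(slip, x, angles, params)
        assert F >= 0.0
        assert F * min(x - E, 0.0) == 0.0


class TestTendonStress:
    @pytest.mark.parametrize("force, area, expected", [(0.0, 5.0, 0.0), (23.1, 1.0, 23.1)])
    def test_definition(self, force, area, expected):
        assert tendon_stress(force, area) == pytest.approx(expected)

    def test_doubling_area_halves_stress(self):
        assert tendon_stress(10.0, 4.0) == pytest.approx(tendon_stress(10.0, 2.0) / 2)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ConfigurationError):
            tendon_stress(1.0, 0.0)


class TestContact:
    def test_open_gap_gives_zero(self, default_model):
        assert contact_force(default_model, "index", {"MCP": 0, "PIP": 0, "DIP": 0}) == 0.0

    def test_linear_penalty(self, default_model):
        # g = L2 sin θ_PIP with zero offset and zero clearance
        L2 = default_model.fingers["index"].phalanx_lengths[1]
        theta = 0.01
        N = contact_force(default_model, "index", {"MCP": 0, "PIP": theta, "DIP": 0})
        assert N == pytest.approx(1000.0 * L2 * math.sin(theta), rel=1e-12)

    @given(tp=st.floats(-0.5, 1.5), td=st.floats(-0.5, 1.2))
    def test_never_negative(self, default_model, tp, td):
        assert contact_force(default_model, "index", {"MCP": 0, "PIP": tp, "DIP": td}) >= 0.0


class TestEquilibrium:
    def test_rest_state_without_loads(self, default_model):
        st_ = solve_equilibrium(default_model, {m: 0.0 for m in MUSCLES})
        assert st_.total_fingertip_force == 0.0
        assert all(f == 0.0 for f in st_.muscle_forces.values())
        assert all(np.all(a == 0.0) for a in st_.joint_angles.values())
        assert st_.residual_norm == 0.0

    @given(
        r=st.floats(3.0, 15.0),
        k_lin=st.floats(0.2, 5.0),
        lever=st.floats(2.0, 8.0),
        x=st.floats(0.5, 8.0),
    )
    def test_single_joint_closed_form(self, r, k_lin, lever, x):
        """θ = r·k·x / (K + r²·k) for one flexor on one torsional joint."""
        model = make_single_flexor_hand(r, k_lin, lever)
        slip = model.muscles["FDS"].slips["index"]
        k = effective_stiffness(slip, model.parameters)
        K = torsional_stiffness_from_linear(k_lin, lever)
        state = solve_equilibrium(model, {"FDS": x, "FDP": 0.0, "ED": 0.0})
        theta = state.joint_angles["index"][0]
        expected = r * k * x / (K + r**2 * k)
        assert theta == pytest.approx(expected, rel=1e-9)
        assert state.slip_tensions[("FDS", "index")] == pytest.approx(
            k * (x - r * theta), rel=1e-9
        )

    def test_spec_worked_single_joint_example(self):
        # r=10 mm, K=75 N·mm/rad, k=2 N/mm, x=3 mm -> θ = 60/275, F ≈ 1.636 N
        model = make_single_flexor_hand(
            r=10.0, k_linear=1.0, lever=5.0, tendon_area=10.0,
            tendon_length=100.0, tendon_modulus=20.0,
        )
        state = solve_equilibrium(model, {"FDS": 3.0, "FDP": 0.0, "ED": 0.0})
        assert state.joint_angles["index"][0] == pytest.approx(60.0 / 275.0, rel=1e-9)
        assert state.slip_tensions[("FDS", "index")] == pytest.approx(
            2.0 * (3.0 - 10.0 * 60.0 / 275.0), rel=1e-9
        )

    def test_equilibrium_certificate(self, calibrated_model, catalog):
        """Re-evaluating the residual on a returned state reproduces the
        convergence claim."""
        for action in catalog[:3]:
            state = solve_equilibrium(
                calibrated_model, action.displacements, mode=action.mode
            )
            res = residual_torques(
                calibrated_model, state.joint_angles, action.displacements, mode=action.mode
            )
            for f in FINGERS:
                free = res[f].copy()
                # clamped joints carry constraint torque, not spring balance
                free[state.clamped[f]] = 0.0
                assert np.max(np.abs(free)) < 1e-5

    def test_resisted_force_monotone_in_displacement(self, calibrated_model):
        """Brute-force sweep: scaling the displacement load up never
        decreases the total fingertip force."""
        totals = []
        for lam in np.linspace(0.2, 1.0, 9):
            state = solve_equilibrium(
                calibrated_model,
                {"FDS": lam * 20.56, "FDP": lam * 21.70, "ED": 0.0},
                mode="resisted",
            )
            totals.append(state.total_fingertip_force)
        assert np.all(np.diff(totals) >= -1e-9)

    def test_angle_range_clamp_is_flagged_not_fatal(self, default_model):
        state = solve_equilibrium(
            default_model, {"FDS": 60.0, "FDP": 70.0, "ED": 0.0}, mode="free"
        )
        assert any(np.any(c) for c in state.clamped.values())
        hi = default_model.fingers["index"].joints["PIP"].angle_range[1]
        assert state.joint_angles["index"][1] <= hi + 1e-12

    def test_bad_inputs_rejected(self, default_model):
        with pytest.raises(ConfigurationError):
            solve_equilibrium(default_model, {"FDS": np.nan, "FDP": 0, "ED": 0})
        with pytest.raises(ConfigurationError):
            solve_equilibrium(default_model, {"FDS": 1.0}, mode="sideways")


class TestEnergyBalance:
    def test_free_flexion_work_equals_stored_energy(self, calibrated_model, catalog):
        """Quasi-static, frictionless: the work fed in through the MTJ
        displacements ends up as tendon + joint-spring elastic energy."""
        action = catalog[0]
        n = 2000
        endpoint = {m: action.displacements[m] for m in MUSCLES}
        lams = np.linspace(0.0, 1.0, n + 1)
        forces = np.zeros((n + 1, len(MUSCLES)))
        prev = None
        state = None
        for i, lam in enumerate(lams):
            x = {m: lam * endpoint[m] for m in MUSCLES}
            state = solve_equilibrium(
                calibrated_model, x, mode="free", initial_angles=prev
            )
            prev = state.joint_angles
            forces[i] = [state.muscle_forces[m] for m in MUSCLES]
        dx = np.array([endpoint[m] / n for m in MUSCLES])
        work = float(np.sum((forces[:-1] + forces[1:]) / 2 @ dx))
        stored = elastic_energy(calibrated_model, state, endpoint, mode="free")
        assert work == pytest.approx(stored, rel=1e-6)


class TestAntagonistBehaviour:
    def test_ed_resists_but_never_pushes(self, calibrated_model, catalog):
        """Free flexion with a lengthening extensor: the ED co-contracts
        (force ≥ 0) yet stays weaker than each flexor."""
        state = solve_equilibrium(
            calibrated_model, catalog[0].displacements, mode="free"
        )
        ed = state.muscle_forces["ED"]
        assert ed >= 0.0
        assert ed < state.muscle_forces["FDS"]
        assert ed < state.muscle_forces["FDP"]
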