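# Methods

## The model

`handflex` is a reduced-order, quasi-static model of the four fingers
(index, middle, ring, little) driven by the extrinsic muscles FDS, FDP and
ED through their muscle–tendon-junction (MTJ) displacements.  It replaces a
full 3D finite-element hand — hundreds of thousands of continuum elements —
with the smallest mechanical system that still carries the quantities of
interest: muscle forces, fingertip forces, their ratios and shares.  Those
quantities are resultants, not field solutions, so rigid phalanges and
torsional joints suffice; bone elastic constants and Poisson ratios play no
role in the reduced statics and are deliberately absent.

Each finger is a planar chain of three torsional joints (MCP, PIP, DIP)
between rigid phalanges.  Each muscle is a rigid body whose prescribed MTJ
displacement `x` (mm, shortening positive) loads one tendon slip per
finger.  A slip is a series spring — tendon (modulus `E_t`, area `A_t`,
free length `L_t`) in series with the retaining ligament/pulley path
(`E_lig`, `A_lig`, `L_lig`):

    k_eff = 1 / (L_t/(E_t·A_t) + L_lig/(E_lig·A_lig))

Its elastic stretch is the applied displacement minus the tendon excursion

    E(θ) = Σ_j r_j·(θ_j + γ·θ_j²/2),

the integral of the instantaneous moment arm `r_j·(1 + γ·θ_j)`; tension is
`k_eff·max(x − E, 0)` — a slack tendon carries nothing.  FDS crosses MCP
and PIP; FDP is the only flexor across the DIP; ED crosses all three with
negative (extension) arms.  Joints carry torsional springs equivalent to
three identical linear springs (left, right, dorsal collaterals) at lever
radius `l`: `K = 3·k·l²`, with one linear stiffness for the MCP class and
one shared by PIP and DIP.  Resisted flexion fixes the proximal phalanges
(freezing the MCP) and presses a rigid plate, modelled as a unilateral
penalty: the pad contact point overlying the DIP joint rises with PIP
flexion by `L2·sin θ_PIP` and meets the plate after an optional clearance;
the reaction is `k_c·max(gap, 0)`.

Equilibrium minimizes the total elastic energy (tendon stretch + joint
springs + contact penalty), a convex piecewise-smooth potential per finger;
fingers decouple because muscles are displacement-driven.  A damped
projected Newton iteration with an energy line search solves each finger's
2–3 unknowns to a residual below 1e-8 of the torque scale; loads ramp
uniformly with warm starts, which maps the experiment's "time" axis to load
fraction.

### Contact placement

The plate reaction is applied at the pad overlying the DIP joint (zero
lever about the DIP by default), so the distal phalanx can keep curling
past the plate edge while the middle phalanx carries the load.  A
fingertip-point contact would pin both IP joints at zero — penetration
would be a sum of nonnegative terms — which contradicts the observed
kinematics of resisted pressing (the DIP is the joint that flexes most) and
would hand the force balance to the FDP via the DIP torque equation,
inverting the measured FDS-dominance.  `contact_offset` moves the resultant
distally and `plate_clearance` delays contact; both default to 0, the
direct reading of a plate set "just in contact" with the finger pad.

## Parameters and defaults

Four material parameters are calibrated (N–mm–MPa units):

| parameter | preset | typical fitted | bounds |
|---|---|---|---|
| tendon modulus (MPa) | 125.31 | ≈ 14 | 10–200 |
| ligament modulus (MPa) | 114.03 | ≈ 8 (weakly identified) | 5–120 |
| IP spring stiffness (N/mm) | 1.0 | ≈ 0.9 | 0.1–10 |
| MCP spring stiffness (N/mm) | 2.0 | ≈ 0.9 | 0.1–10 |

The fitted tendon modulus lands far below cadaveric tendon moduli because
`k_eff` is an *effective* transmission stiffness: it absorbs every source
of series compliance the rigid-bone reduction removes (soft tissue, pulley
bowstringing, oversized model cross-sections).  The calibration targets
resultant forces, so only the products `E·A/L` matter.

Geometry defaults are anthropometric and configurable (YAML): phalanx
lengths per finger from standard hand tables; flexor moment arms 10.5–11.5
mm (MCP), 6.5–7.0 mm (PIP), 4.8 mm (DIP) at the index, scaled 0.84–1.0
across fingers; extensor arms (−10.5, −6.0, −4.0) mm — sized so that the
extensor's excursion at the relaxed posture matches its measured passive
MTJ displacement (≈ −12.5 mm), which by the active/passive decomposition
is a lower bound on that excursion.  Moment arms grow with flexion
(`arm_growth` 0.25/rad for FDS, 0.40/rad for FDP, 0 for ED), the
bowstringing seen in tendon-excursion studies; the FDS free tendon is
shorter (230 vs 270 mm) and threads a shorter pulley path (15 vs 30 mm
series ligament), making its transmission stiffer than the FDP's — this is
what lets the superficial flexor produce more force from less displacement.
Joint spring lever radii scale with joint size (6/5/3.5 mm for
MCP/PIP/DIP), so the DIP is torsionally the most mobile joint.  Joint
ranges are 0–90° (MCP), 0–100° (PIP), 0–70° (DIP).

## Calibration

The fit is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) in log-parameter space.  Residuals are the four
resisted-action plate-reaction errors (N) and, when a free action carries a
posture observation, the three mean-joint-angle errors weighted at
4 N/rad — the ratio of the assumed force noise (0.2 N) to posture noise
(0.05 rad).  The posture channel matters twice over: the resisted data are
nearly collinear (a stiff-joint parameter corner reproduces the four forces
about as well as the physiological soft-joint solution but flexes almost
nothing in free flexion), and the MCP spring is structurally invisible to
resisted actions because the proximal phalanges are fixed.  The free
action's flexion pattern — quantified as the clinical resting posture, MCP
≈ PIP ≈ 40°, DIP ≈ 20° — selects the physiological branch and identifies
the MCP stiffness.  Diagnostics report parameters sitting on bounds, a
flat-profile flag for the ligament modulus (it shares a compliance ridge
with the tendon modulus), and whether the MCP stiffness was identified.

Four observations cannot pin four parameters exactly; the fit retains
percent errors of roughly 0.5–10% across the resisted actions, reported
per action with their min/max envelope.

Sensitivity profiles (fingertip force vs one parameter, others fixed) show
the expected signs on the *preset* model: increasing in both moduli,
non-increasing in the spring stiffnesses.  Around the *fitted* point such
profiles are necessarily non-monotone — least squares drives the local
force sensitivity of every interior parameter to zero — so the correlation
statements describe the adjustment phase, not the optimum.

## Synthetic studies and parameter recovery

`make_geometry` draws per-finger phalanx lengths and arm scales within ±8%
of the defaults (seeded, deterministic, homogeneous in an overall scale
factor, finger ordering preserved).  `make_protocol` generates resisted
actions with increasing FDS endpoints, FDP endpoints 1.05–1.5× larger, ED
zero, optionally preceded by a free action with a lengthening extensor;
the measured five-action protocol is available verbatim.
`simulate_observations` adds zero-mean Gaussian noise: 0.2 N on fingertip
forces (platform resolution) and 0.05 rad on free-flexion posture angles;
an optional 0.5 mm MTJ-displacement noise mirrors ultrasound marking error.
`recovery_experiment` repeats simulate→calibrate with one geometry and
fresh noise per replicate, scaling both noise channels together so zero
noise is exactly noiseless, and reports per-parameter relative bias and
RMSE.  Noiseless recovery is exact; under noise the tendon/ligament ridge
inflates the moduli RMSE well above the spring-stiffness RMSE, which is the
identifiability structure the diagnostics advertise.

What the generator does not emulate: inter-trial variability of a real
subject's displacements (single trial per action in the study), non-Gaussian
platform drift, and any geometry error correlated across fingers.  Passing
recovery therefore validates the estimation pipeline, not the anatomical
fidelity of the geometry.

## Numerical choices

Solver tolerance 1e-8 relative to the torque scale; 200 Newton iterations
with 40-step energy backtracking; joints clamped at a range bound are
reported in the state rather than failing the solve; a zero-displacement
load returns the rest state directly.  Trajectories use 50 uniform load
steps (doubling changes final forces by < 0.5%); calibration evaluates
final states through a 6-step warm ramp, exploiting the convexity of the
per-finger potential (final states are path-independent).  The energy
balance test integrates work with 2000 trapezoid steps to meet its 1e-6
relative tolerance.  The acceptance pipeline (calibrate + run five actions)
takes well under a minute on one CPU; the 20-replicate recovery study a few
minutes.

## Known limitations

* The mid-ramp muscle-force **plateau** seen in free flexion in the source
  experiment does not emerge here: at the calibrated stiffness ratio the
  quasi-static response is stretch-dominated and the force curves are
  smoothly concave.  The plateau appears to be a sequential-joint/dynamic
  feature of an explicit transient solution.  The plateau detector and the
  validation report treat it honestly: `validate_free_flexion` reports the
  check as failed rather than relaxing its definition.
* The flexor-share jump between the two lightest resisted actions
  (≈ 49% → 63% FDS) is steeper in the measurements than any smooth
  quasi-static transmission can produce; the model lands near 54% → 62%.
* Nominal tendon stress is force/area; stress concentrations at joints are
  a continuum-mechanics feature outside this model's scope.
* Single subject, single geometry: defaults are one plausible hand, not a
  population model.
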