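# Output file schemas

Units are N–mm–MPa (angles in radians) throughout.

## `action<N>_trajectory.csv`

One row per load step of a uniformly ramped action.

| column | meaning |
|---|---|
| `step` | load step index, 0 = rest |
| `load_fraction` | fraction of the displacement endpoints applied, 0..1 |
| `angle_<finger>_<joint>` | flexion angle (rad) of MCP/PIP/DIP on index/middle/ring/little; 0 = straight |
| `force_FDS`, `force_FDP`, `force_ED` | muscle force (N), sum of the four slip tensions |
| `tip_<finger>` | plate reaction (N) on that finger (0 in free mode) |
| `tip_total` | total fingertip force (N), sum over fingers |
| `residual_norm` | equilibrium residual (N·mm) over free, unclamped joints |

## `action<N>_final.json`

Full final equilibrium state: per-finger joint angles, per-slip tensions,
muscle forces, fingertip forces, residual norm, and which joints (if any)
ended clamped at a range limit.

## `calibration.json` / `calibration_report.txt`

Fitted parameter set (`tendon_modulus` MPa, `ligament_modulus` MPa,
`ip_spring_stiffness` N/mm, `mcp_spring_stiffness` N/mm), per-action
observed and predicted plate reactions with percent errors and their
min/max, convergence diagnostics, which parameters sit on a bound, and
identifiability flags (`ligament_weakly_identified`, `mcp_identified`).

## `validation.json`

Free-flexion validation: per-check booleans (all joints flexed, ranges
respected, flexor force plateau found, extensor force nonnegative), final
muscle forces, final mean joint angles, detected plateau intervals.

## `recovery.json`

Parameter-recovery report: ground-truth parameters, per-parameter relative
bias and relative RMSE over replicates, and the fraction of replicates
whose calibration converged.

## `summary.json` (simulate)

Per-action final muscle forces and total fingertip force, flexor shares
(FDS/FDP percent of total flexor force), and — over the resisted actions —
the mean muscle-force-to-fingertip-force ratios for FDS and FDP.

## Actions YAML (input)

`actions:` list with `action_id`, `mode` (`free`/`resisted`),
`displacements` (mm per muscle, shortening positive), optional
`display_reading` (N); `plate_resistance` (N) is added to display readings
to obtain observed fingertip forces.
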