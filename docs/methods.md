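# Methods

## Model overview

`cerebroflow` is a lumped-parameter ("zero-dimensional") model of the human
cerebral circulation. The vasculature is a resistor–capacitor network: every
compartment (a vessel or a population of identical parallel vessels) is a
hydraulic resistor, and the conduit arteries of the Circle of Willis (ICA, BA,
MCA, ACA1/2, PCA1/2, PCoA, ACoA) plus the veins and venous sinuses carry a
Windkessel capacitor representing volume storage by the elastic wall. A
capacitor compartment is split into halves *a* and *b*, each holding half the
length and half the resistance, with the capacitor at the node between them.

The network spans both sides of a complete Circle of Willis and, per side,
three microcirculatory territories (middle, anterior, posterior), each a
series chain of large arterioles (LA), small arterioles (SA), capillaries
(CAP), small venules (SV) and large venules (LV) between nodes P1…P5, draining
through a shared venous pathway P6 → V → P7 → VS → PV. Leptomeningeal
collaterals join the middle territory's P2 node to the anterior (COL_am) and
posterior (COL_pm) P2 nodes; they and the arterioles are vasoactive. The
compartment geometry (diameter, length, vessel count), the compartment
resistances and the capacitances are shipped as a JSON vessel table
(`src/cerebroflow/data/control_network.json`).

Fixed constants: blood viscosity μ = 0.04 Poise; intracranial pressure
Pic = 9.5 mmHg; venous outflow pressure PV = 9.5 mmHg; arterial
distensibility 4.01×10⁻⁷ cm²/dyn with venous distensibility 8× arterial.
Resistance follows Poiseuille's law, R = 128Lμ/(nπD⁴); capacitance is
distensibility × cylindrical volume. Pressures cross the interface in mmHg
and all CGS arithmetic uses the single conversion constant
1 mmHg = 1333.22 dyn/cm² (`cerebroflow.units`).

Two deliberate deviations from naive recomputation, both because the tabulated
control state—not the rounded tabulated diameters—is the authoritative anchor:

* The communicating arteries (PCoA, ACoA) and the veins (V, VS) use their
  tabulated resistances verbatim; Poiseuille from their tabulated diameters is
  inconsistent with those values, and it is the resistances that determine the
  control pressure distribution. Vein diameters are used only for volume
  (capacitance).
* Vasoactive and microcirculation resistances at non-control states scale
  from the tabulated control resistance, R = R_c (n_c/n)(D_c/D)⁴, rather than
  being recomputed from scratch. This preserves the Poiseuille exponents
  while keeping the control state an exact fixed point (raw recomputation
  from the rounded diameters shifts the tabulated resistances by up to ~1.5%
  and the control pressures by a few tenths of a mmHg).

## Inflow waveform

The inflow boundary Pa(t) is a periodic synthetic carotid pressure wave:
a half-cosine systolic upstroke over 35% of the period followed by an
exponential diastolic decay back to the foot. The targets are the control
systolic/diastolic pressures 121/83 mmHg and a period mean of 99.2 mmHg (the
control time-averaged inflow pressure); the one free shape parameter (the
decay rate) is solved by Brent's method so the period mean meets its target.
The period defaults to 1 s (60 bpm) and is configurable. The true measured
shape this stands in for is not available to the package, so time-resolved
pressure/flow traces are qualitative; maxima, minima and period means are
quantitative.

To impose a different mean arterial pressure the control wave is transformed
pointwise, P_new = a·P_cont + b. Systolic pressure is assumed linear in
diastolic with slope 1.58; anchoring the line at the control point gives
S = 1.58·Dy − 10.14, and combining it with MAP = Dy + (S − Dy)/3 yields
S(MAP) and Dy(MAP) (full-precision coefficients are derived symbolically at
import and cross-checked against their 3-decimal forms S = 1.324·MAP − 5.664,
Dy = (MAP + 3.38)/1.193). Solving S = a·Sc + b, Dy = a·Dyc + b fixes the
transform uniquely per MAP. Supported MAP range: 30–200 mmHg.

## Pressure system

At each of the 18 capacitor nodes, volume storage balances net inflow:
C d(P − Pic)/dt = ΣQ_in − ΣQ_out; the 39 junction nodes obey Kirchhoff's
current law. With fixed resistances this is a linear index-1 DAE. Junction
pressures are eliminated by a Schur complement on the resistive subgraph,
leaving an explicit linear ODE in the capacitor pressures integrated with
BDF (rtol 10⁻⁶, atol 10⁻⁴ mmHg; the exact Jacobian is the reduced system
matrix). The RC time constants are ~10⁻⁴–10⁻³ s, so a 2 s window with the
resistive steady solution as the initial condition reaches the periodic
regime within milliseconds. Period averages are trapezoidal means over the
final period (200 samples per period).

Because the fixed-resistance system is linear and time-invariant, the
period-averaged pressures in the periodic regime equal the steady resistive
solve (capacitor branches open) at the waveform's time average. The package
exposes this resistive solve as a first-class oracle, verifies the
equivalence to < 0.2 mmHg at every node in the tests, and uses it as the fast
averaging mode inside the slow regulation loop.

## Vasoregulation

Tracked vasoactive compartments (6 LA, 6 SA, 4 COL) each carry a diameter D
and an activation A ∈ [0, 1]:

* dD/dt = (1/τ_d)(D_c/T_c)(T − T_total), with Laplace wall tension
  T = (P̄ − Pic)·D/2 evaluated at the compartment's midpoint average
  pressure. Since T_c = (P_c − Pic)·D_c/2, the prefactor D_c/T_c equals
  2/(P_c − Pic); the equivalence is asserted symbolically in the tests.
* dA/dt = (A_total − A)/τ_a, A_total = 1/(1 + e^(−S_tone)), with
  S_tone = C_myo·T − C_shear·|τ| − C_meta·S_meta + C''_tone (the LA class has
  no metabolic term). Wall shear is τ = 32μq/(πD³) from the period-averaged
  per-vessel flow.

τ_d = 1 s and τ_a = 60 s. Total tension is the Carlson–Arciero sum of a
passive exponential and an activation-weighted Gaussian active term:
T_total = C_pass·exp(C'_pass(D/D₀ − 1)) + A·C_act·exp(−((D/D₀ − C'_act)/C''_act)²).

The tension/tone scale coefficients are not taken from the literature — they
are *calibrated* per compartment so that the control state (tabulated
diameters; activation 0.5 in arterioles, 0.99 in collaterals) is an exact
equilibrium of both ODEs: C_pass and C_act are solved from
T_total(D_c, A_c) = T_c given a passive fraction, and C''_tone from
S_tone(control) = logit(A_c). What remains configurable
(`RegulationShape`) are dimensionless shapes and gains, with defaults chosen
once as physiologically motivated magnitudes:

| parameter | default | meaning |
|---|---|---|
| C'_pass | 7 | steepness of the passive wall (relative-diameter e-folding) |
| C'_act, C''_act | 1.0, 0.5 | active tension peaks at D₀ with width 0.5·D₀ |
| passive fraction | 0.3 | share of control tension carried passively (active tone dominates, giving the smooth muscle a wide working range) |
| myogenic gain C_myo·T_c | 10 (LA, SA), 5 (COL) | stimulus swing per relative tension change; sets the autoregulation plateau strength |
| shear gain C_shear·τ_ref | 1 | τ_ref is the control shear (floor 10 dyn/cm² for the nearly-flowless control collaterals) |
| metabolic gain C_meta·S_meta,c | 2 (SA), 4 (COL), 0 (LA) | stimulus swing per relative change of the conducted signal; the collateral value lets a post-occlusion signal (≈2.5× control) overcome logit(0.99) ≈ 4.6 and dilate the collaterals |

With these defaults the model autoregulates: regional flow holds within
roughly ±20% of control for MAP 60–110 mmHg and breaks away at the extremes,
non-occluded flow rises only ~9% when MAP is raised to 120 mmHg, while
post-occlusion middle-territory flow rises ~30–40% for the same change and
grows approximately linearly with MAP — the qualitative fingerprints of
disturbed autoregulation after MCA occlusion. The activation trajectory stays
in (0, 1) because its target is a logistic and the relaxation is linear.

## Oxygen transport and the conducted signal

This module is a documented simplification (the full oxygen and
conducted-response formulation the tone model descends from is outside this
package's scope). Each territory consumes M0 (default 12 cm³O₂/100 cm³/min)
over a tissue volume defaulting to 35 cm³ per cm³/s of control regional flow
(≈0.35 control extraction at M0 = 12, carrying capacity 0.2 cm³O₂/cm³,
inflow saturation 0.97). The demand is split across LA/SA/CAP/SV/LV by fixed
fractions 0.10/0.20/0.50/0.15/0.05; crossing compartment k drops saturation
by f_k·demand/(|Q_k|·c₀), clamped at zero. Conduit arteries extract nothing.
When the middle-left LA loses its feed (occlusion), the middle-left chain is
evaluated along the collateral route (anterior arteries → LA_a → COL_am →
SA_m → …).

Venules generate a dilatory signal (1 − S̄)·length that is conducted upstream
with exponential attenuation (length constant 1 cm) to the small arterioles;
collaterals receive the attenuated signals of both territories they join,
since collateral flow may run in either direction.

## Control calibration

The control state fixes the anchors: fixed activations (0.5/0.99), tabulated
diameters, and an inner iteration on microcirculation vessel numbers — venule
diameters follow the arterioles by fixed ratios (SV/SA ≈ 2.155, LV/LA ≈ 2.149,
the tabulated control ratios), resistances are updated by Poiseuille scaling,
the pressure system is solved and period-averaged, compartment flows follow
from Ohm's law, per-vessel flows from target shears (q = πτD³/32μ), and
numbers are set to compartment flow / vessel flow until convergence (relative
tolerance 10⁻⁶, default cap 100 iterations). Target shears default to the
values implied by the shipped table, making the table the procedure's exact
fixed point; the iteration contracts geometrically (rate ≈ the
microcirculation's share of total path resistance, ~0.9), so recovery from a
large perturbation takes a few hundred iterations. Control midpoint pressures
are arithmetic means of the flanking node averages: (P1+P2)/2 for LA,
(P2+P3)/2 for SA, (P2 of both joined territories)/2 for collaterals.
Calibration can run in fast (resistive) or faithful (pulsatile DAE) averaging
mode; both agree to < 0.2 mmHg.

## Scenarios and the two-timescale loop

A scenario fixes the MAP target, occlusion flag, distensibility scale, oxygen
demand and durations. Occlusion of the left MCA is structural: both halves of
the compartment and the nodes PMCA,l and P1,ml are removed (17 differential
states remain), and the orphaned middle-left LA is dropped from tracking; the
middle-left territory is then perfused only through the collaterals at P2,ml.

The slow system (diameters/activations) is integrated with Heun's method,
default step 0.25 s over 200 s. The calibrated tension stiffness gives the
diameter equation a relaxation rate of ~4 s⁻¹, for which 0.25 s is safely
inside the explicit stability region; halving the step changes final flows by
< 0.5% (tested). At each stage the vasoactive resistances are rebuilt from
the current diameters and the pressure system is re-averaged — by the
resistive oracle in the default fast mode, or by a fresh 2 s DAE solve in
`pulsatile` mode (both modes agree; tested). Pulsatile diagnostics
(oscillation amplitudes, time dynamics) are always produced by a full DAE
solve at the final state. The pipeline is deterministic end to end; repeated
runs are bitwise identical.

Problem sizes used throughout the shipped tests and the reproduction script:
the full 59-node network, 2 s pressure windows at 200 samples/period, 200 s
outer horizons, and 6–8-point MAP sweeps; these keep the complete suite at
about half a minute on one CPU.

## Known limitations

* The inflow waveform shape and the tension/tone coefficients are this
  package's own calibrated constructions; time-resolved traces and the exact
  magnitudes of simulated responses (percent flow recovery, autoregulation
  slopes) are therefore qualitative, while the control state, the waveform
  algebra and the pressure-averaging identities are quantitative.
* Capacitances are constant (no pressure-dependent compliance), intracranial
  pressure is fixed, and there is no CO₂ reactivity, no neurogenic control,
  no wall remodeling, and no wave propagation (lumped elements cannot carry
  pulse waves).
* The oxygen module ignores radial diffusion and hemoglobin dissociation;
  saturations are convective book-keeping for the conducted signal.
* Only complete Circle-of-Willis anatomy and total left-MCA occlusion are
  supported; partial stenoses and anatomical variants are not.
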