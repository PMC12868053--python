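# Methods

This note documents the model equations, the parameter defaults and
their provenance, the numerical choices, and the limitations of the
package.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope

The package implements the *physical* half of a human simulation
model: heat and blood transport given fixed physical properties.  There
is no autonomic regulation - no vasomotion, sweating, shivering or
baroreflex - so the only operating point at which the model is expected
to reproduce physiology is the calibration condition itself: supine,
thermoneutral (28 degC air, 40 % relative humidity), heart rate
62 beats/min.  Scenario machinery (ambient state, posture elevations,
heart rate) exists so that a regulation layer can later drive it.

## Thermal network

Sixteen segments; four concentric compartments each (core, muscle,
fat, skin), with the head resolving brain and skull and the chest the
two heart pools and the lung.  Vessels are explicit nodes: per-segment
artery and vein, plus superficial veins in the limbs.

* Compartment balance: storage = metabolism + conduction + perfusion
  advection + piston-flow vessel exchange - environmental losses.
* Piston flow (neck, abdomen, upper/lower arms, thighs, legs): blood
  traversing the segment equilibrates exponentially with the core,
  effective conductance `rho c Q (1 - exp(-TC/(rho c Q)))`.  The
  artery/vein energy balances are quasi-steady (no heat capacity).
* Counterflow: artery and vein exchange like a counterflow heat
  exchanger with NTU = TC/(rho c Q_ve); the balanced-flow limit
  `rho c Q NTU/(1+NTU)` replaces the general formula when
  |1 - Q_ve/Q_ar| < 1e-6.  For Q_ve > Q_ar the algebraically identical
  form with a negative exponent is used (overflow-safe).
* Head, hand and foot vessels and all superficial veins are perfectly
  mixed pools.
* Respiration: `C_res = 0.0014 M (34 - T_air)` W and
  `E_res = 0.0173 M (5.87 - p_air[kPa])` W applied to the lung node -
  the classical thermophysiology formulations, shipped as editable
  defaults because the source model's own formulas are not published
  with it.
* Skin latent loss: insensible diffusion only, a fixed wettedness
  (default 0.06) times the maximal evaporative capacity
  `16.5 (h - h_r) A (p_sat(T_sk) - p_air)`; sweating belongs to the
  regulation layer.

Given the flows, every equation is linear in the temperatures, so the
implicit 10 s step is one dense solve of a ~110-node system
(unconditionally stable; the matrix is LU-factorised once per flow
update).  The only lagged term is the skin latent loss (evaluated at
the previous skin temperature).  Steady state is declared at
|dT/dt| < 2e-6 K/s at every node; at that tolerance the global energy
closure is within 0.5 %.

### Conductances

Radial conduction between concentric layers uses shell formulas
(cylinders `2 pi k l / ln(r_out/r_in)`, head as a sphere
`4 pi k/(1/r_in - 1/r_out)`) evaluated from each layer's mid-radius to
the interface, in series.  Vessel-tissue composites combine an
in-vessel film coefficient (default 1000 W/m2K) and a tissue path
coefficient (default 45 W/m2K) in series over the printed vessel
surface areas; the arterio-venous path adds both films around a tissue
coefficient of 30 W/m2K.  Head vessel conductances are zero (the head
vasculature does not admit the concentric simplification).  These film
coefficients are package defaults: the source supplement that derived
them is not available, and they mainly set the strength of counterflow
pre-cooling, a second-order effect at baseline.

### Surface coefficients

Combined convective+radiative coefficients per segment default to
6.4-7.2 W/m2K (hands/feet 7.2-8.0, head 7.0): representative of a
supine subject in still air with a partially occluded radiant
environment.  They are the package's stand-in for manikin-measured
values and were fixed, together with the other defaults, to give a
thermoneutral operating point (energy closure, core ~36.5 degC, skin
~33-35 degC) at the baseline condition before the acceptance suite was
written.

## 1-D arterial tree

77 named systemic arteries (Westerhof/Avolio-style topology assembled
from the printed table; bilateral vessels duplicated).  Governing
equations: area/flow conservation with momentum flux Q^2/A, elastic
tube law `P = beta (sqrt(A/A0) - 1)`, `beta = E h_rel/(1 - sigma^2)`
(sigma = 0.5, incompressible wall), gravity `A g dH/dx` (edge-centred
differences; supine baseline has H = 0) and boundary-layer friction
`2 pi r nu/delta Q/A` with delta = 0.9 mm by default (order of the
oscillatory boundary-layer thickness sqrt(nu T); configurable, kept
below the smallest reference radius).

Numerics: two-step (Richtmyer) Lax-Wendroff on a per-artery uniform
grid, dx = l/ceil(l/5 mm), at least 3 nodes; the pressure gradient is
split into a conservative flux plus a reference-area taper source.
The CFL ratio is monitored every step.  Junctions enforce flow
conservation and static-pressure continuity together with the outgoing
Riemann invariant (u +- 4c for this tube law) of every connected end,
by damped Newton iteration to 1e-12.  The root prescribes the aortic
valve flow (backward characteristic closes the area); terminals
prescribe the peripheral pressure (tube-law inversion plus forward
characteristic).

After the characteristic closures fix the boundary *flows*, the
boundary-node *areas* are updated conservatively as half-cells from the
half-step face fluxes.  This makes the tree's trapezoidal volume change
exactly by the boundary flow integrals - without it the node-centred
scheme swallowed ~5 mL per cycle at the 78 boundary/junction ends,
which both violated conservation and prevented a true periodic steady
state.  The price is that boundary nodal areas are half-cell averages
rather than the pressure-continuous interface states; the interface
residuals (flow 1e-12, pressure machine-level) hold at the junction
solve itself, and nodal continuity across junctions is
discretisation-level (~1e-3 relative).

## 0-D closed loop

Each terminal artery feeds a four-route peripheral circulation:

* series split of the route's total viscous resistance R_T: arteriole
  90 %; the remaining 10 % distributed over distal arterial end,
  capillary, venule and vein as 17 : 21 : 6.5 : 1.5 renormalised;
* scaling laws L = lambda sqrt(R_T), C = gamma/R_T with constants
  inherited from the single-route reference circuit (gamma:
  arteriole 1.6 s, capillary 3.2 s, venule 21 s, vein 60 s - chosen so
  the summed compliances give physiological arterial/venous capacitance
  and a stressed blood volume of ~1.6 L);
* four parallel routes (core/muscle/fat/skin) whose resistances are
  inversely proportional to the route flow fractions; this preserves
  the capillary and venule node pressures of the single-route circuit
  exactly at the reference flow.  The four arteriole branches share one
  compliance; the collecting vein is shared.

Veins drain to superior (head/arms/chest), inferior (legs; chained
through the abdominal element) or abdominal vena cava, each a basic
R-L-C unit.  Four heart chambers use time-varying elastance
`P = (E_A e(T) + E_B)V + S dV/dt` with piecewise-cosine activation
(atrial activation wraps across the cycle; ventricular contraction
occupies fractions 0.02-0.32-0.47 of the period), valves obey
`P_up - P_dw = Q R + Q^2 B + L dQ/dt` with the flow clamped at zero
under an adverse gradient (state clamping, not resistance switching,
so RK4 sees smooth dynamics within each valve phase).  Pulmonary
compartments use `P = E0 Phi exp(V/Phi) + S dV/dt`.  Chamber,valve and
pulmonary constants are editable defaults in the tradition of published
closed-loop models, tagged `provenance: literature` in the data file.

Integration: classical RK4 at dt = 0.1 ms (snapped so an integer
number of sub-steps tiles the cardiac period exactly).  1-D/0-D
exchange happens every sub-step, lagged by one: the 0-D supplies
terminal pressures (arteriole-node pressure plus the distal-end drop at
the previous terminal flow) and receives the fresh terminal flows; the
aortic valve flow drives the 1-D root against the root tube-law
pressure.

Initial state: volumes at reference (diastolic-like) pressures, zero
flows, cardiac phase 0.5; the periodic steady state makes the choice
immaterial.  Convergence: cycle-to-cycle relative change of stroke
volume, mean root pressure and every element volume below 1e-3.  Two
refinements to the volume metric: the relative scale is floored at
0.1 % of total monitored volume, and the change is also compared two
cycles back.  Both exist because a weakly damped slosh between the
hand-artery blood columns and their small shared-arteriole compliances
(~0.5 mL elements, sub-microlitre amplitude, decay time of order a
hundred cycles) otherwise stalls the detector on motion that is
physiologically meaningless while stroke volume and pressure have
converged to ~1e-7; a genuine drift accumulates over two cycles and is
still caught.

## Calibration

Groups mirror the printed baseline flow table (segment-group x
compartment; bilateral limb groups per side).  After each converged
forward run every group's per-route resistances are updated by damped
proportional control on the log-resistance,
`R_T <- R_T (Q_sim/Q_target)^0.7`, and all element values re-derived
through the scaling laws (so the 90/10 split and the L/C couplings are
preserved exactly at every iterate).  Parameter updates are applied to
the running model without restarting: compliance volumes are rescaled
to keep element pressures continuous, and the total stressed blood
volume is then restored by distributing the rescaling residual over
the collecting veins in proportion to compliance - changing
resistances must not add or remove blood, and cardiac output is
preload-determined, so an unconserved volume would bias every flow
uniformly in a way resistance updates cannot remove.  Within a group the relative
shares of member routes are fixed anatomical weights (shipped in the
route map); only the group aggregate is observable from the targets.
The group updates only shape the flow *distribution*.  Two global
modes are unobservable to them: the total flow is preload-determined
(the closed loop conserves its stressed volume, and the C ~ 1/R_T
coupling stiffens the veins as resistance rises, cancelling the
afterload effect - measured: a +10 % uniform resistance scaling moves
cardiac output by only +0.5 % while the mean pressure rises ~10 %),
and consequently the absolute pressure level is undetermined by flow
targets alone.  The calibration closes both modes with two scalar
trims, damped like the group updates: the stressed blood volume drives
the total flow to the target sum, and a uniform resistance factor
anchors the aortic mean pressure to the standard-person reference
(93 mmHg, shipped default).  Both the stressed-volume level and the
mean-pressure anchor are unprinted parts of the standard-person
description, playing for the global modes the role the measured
distribution plays for the resistances.

Default tolerance 2 % on every group and on the pressure anchor; the
shipped configuration converges in 3 iterations (the first forward run
needs ~12 cycles, warm restarts ~8).

## Problem sizes and costs

Baseline configuration: ~1900 1-D grid nodes, 915 0-D state variables,
9677 sub-steps per cardiac cycle, 110 thermal nodes.  A converged
calibrated baseline (calibration plus final run plus thermal steady
state) is a few minutes on one CPU with the numba kernels; a single
cardiac cycle is ~1.5 s.

## Known limitations

* No autonomic regulation: away from the thermoneutral supine baseline
  the predictions are *physical* responses only.
* The ankle-brachial systolic index sits below 1 (the ankle systolic
  lands slightly below the aortic-root systolic, while the brachial is
  more strongly amplified); the pulse-pressure amplification from the
  root to both sites is reproduced, but only marginally at the ankle.
  Distal systolic amplification in the legs is sensitive to the
  friction model and the terminal impedance split.
* Vessel collapse, non-Newtonian rheology and curvature losses are not
  modelled; the tube law requires positive transmural area.
* The synthetic stand-ins for unavailable reference constants (film
  coefficients, surface coefficients, heart/pulmonary constants) are
  single defaults, not fitted distributions; results at other ambient
  conditions should be read qualitatively until a regulation layer and
  condition-specific coefficients exist.
* Only stressed blood volume is represented (V = C P); total volume in
  the loop (~1.6 L) is therefore the stressed fraction of whole-body
  blood volume, not the anatomical 5 L.
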