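# hemotherm

A physical (non-regulated) simulator of body temperature, blood
pressure and blood flow in a standard young adult male, for
thermophysiology and cardiovascular modelling work: it couples a
16-segment thermal network of the body with a closed-loop
cardiovascular model (a 77-artery one-dimensional pulse-wave tree plus
a lumped-parameter circulation), and ships the calibration procedure
that tunes the peripheral resistances to a measured baseline blood-flow
distribution.

## The model

**Thermal network.** Each body segment (head, neck, chest, abdomen and
the paired limb segments) is a set of concentric tissue compartments
(core/muscle/fat/skin; the head resolves brain and skull, the chest
the heart chambers and lung).  Each compartment obeys

    C_I dT_I/dt = M_I + sum_J (TC_I,J + rho c Q_I,J)(T_J - T_I)
                  - C_res - E_res - E_sk + q_I,ar + q_I,ve

with conduction `TC`, blood-borne advection `rho c Q`, respiration and
insensible skin losses, and quasi-steady piston-flow heat exchange with
the segment's artery and vein, including arterio-venous counterflow
exchange (NTU form).  The system is linear in the temperatures for
given flows, so the implicit 10 s step is a single dense solve.

**Cardiovascular model.**  The 77 major systemic arteries are solved as
1-D mass/momentum conservation with an elastic tube law

    P = (E h / (r0 (1 - sigma^2))) (sqrt(A/A0) - 1)

via the two-step Lax-Wendroff scheme, with gravity and boundary-layer
friction, junctions closed by Riemann invariants and Newton iteration.
Each terminal artery drains into a four-route (core/muscle/fat/skin)
RLC peripheral circulation; veins collect into three venae cavae, four
time-varying-elastance heart chambers with valve dynamics
(`P_up - P_dw = Q R + Q^2 B + L dQ/dt`) and two exponential pulmonary
compartments close the loop (RK4, dt = 0.1 ms).  The per-heartbeat mean
flows feed the thermal network every 10 s.

**Calibration.**  Per-route total resistances R_T are tuned by damped
proportional control until the cycle-averaged flows reproduce the
packaged baseline flow table (ultrasound-based measurements of an
average Japanese male in his 20s, supine at 28 degC / 40 % RH, heart
rate 62), while preserving the 90 % arteriole share of R_T and the
scaling laws L ~ sqrt(R_T), C ~ 1/R_T.  Two scalar trims close the
modes that group-wise resistance updates cannot reach in a closed
loop: the stressed blood volume sets the total flow, and a uniform
resistance factor anchors the aortic mean pressure to the
standard-person reference.

## Worked example

```python
from hemotherm import load_standard_person
from hemotherm.calibration import FlowTargets, calibrate_peripheral_resistances
from hemotherm.driver import ScenarioConfig, run_baseline

params = load_standard_person()                       # packaged tables
config = ScenarioConfig()                             # 28 degC / 40 % RH, HR 62
targets = FlowTargets.from_parameter_set(params)
params, report, model = calibrate_peripheral_resistances(targets, params, config)
bundle = run_baseline(config, params, model=model)

print(round(bundle.cardiac_output_ml_min))            # 4979
print(bundle.pressures_mmHg["brachial"])              # {'systolic': 132.2, 'diastolic': 77.4, 'mean': 93.1}
print(round(bundle.temperatures[("head", "brain")], 2))   # 36.48
print(bundle.flows[bundle.flows.group == "head_brain"])
#         group  simulated_ml_min  target_ml_min  rel_error
#    head_brain            914.12          904.0      0.011
```

The cardiac output is the cycle-averaged aortic-valve flow of the
converged loop (the baseline flow table sums to 4930 mL/min; the
calibration stops once every row is within 2 %).  Pressures are
max/min/mean of the converged mid-artery waveforms; temperatures are
the thermal-network steady state.  `hemotherm simulate --out results/`
runs the same pipeline from the command line and writes
CSV/JSON tables; `hemotherm report --bundle results/` prints them.

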