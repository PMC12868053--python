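# Lumped-parameter (0-D) circulation defaults for the standard adult model.
#
# Units are stated per key.  Pressure-based quantities use clinical units
# (mmHg, mL, s) and are converted to strict SI by the loader.
#
# provenance values:
#   printed     - value printed in the primary anatomical/physiological tables
#   literature  - adopted from the closed-loop circulation modelling literature
#                 (Westerhof/Avolio-style arterial trees; Liang-type closed loops)
#   default     - editable package default chosen to give a physiological
#                 baseline operating point; no printed source available
schema_version: 1

blood:
  density_kg_m3: 1050.0          # provenance: literature
  specific_heat_J_kgK: 3850.0    # provenance: literature
  kinematic_viscosity_m2_s: 3.3e-6   # provenance: literature
  boundary_layer_m: 9.0e-4       # friction boundary-layer thickness; provenance: default

heart_rate_bpm: 62.0             # provenance: printed

# Series split of the total viscous resistance R_T of one peripheral
# circulation.  The arteriole takes 90 % of R_T; the remaining 10 % is
# distributed over the other four elements in proportion to the classical
# single-route ratios 17 : 21 : 6.5 : 1.5 (distal arterial end, capillary,
# venule, vein), renormalised among themselves.
resistance_split:
  arteriole_share: 0.90          # provenance: printed
  literature_ratios:             # provenance: literature (single-route model)
    distal_arterial_end: 17.0
    capillary: 21.0
    venule: 6.5
    vein: 1.5

# RLC scaling laws: L = lambda * sqrt(R_T), C = gamma / R_T, with the
# proportionality constants inherited from the single-route reference
# circuit.  gamma in [s]; lambda in [mmHg*s^2/mL / sqrt(mmHg*s/mL)].
scaling_constants:               # provenance: default (reference circuit)
  gamma_s:
    arteriole: 1.6
    capillary: 3.2
    venule: 21.0
    vein: 60.0
  lambda_mmHg:
    arteriole: 0.02
    capillary: 0.01
    venule: 0.01
    vein: 0.02

# Reference pressures used to seed per-route total resistances before
# calibration and to initialise element volumes (mmHg).
reference_pressures_mmHg:        # provenance: default
  arterial: 80.0
  arteriole_node: 75.0
  capillary: 10.0
  venule: 6.5
  vein: 5.5
  vena_cava: 4.5
  perfusion_drop: 83.0           # mean arterial minus vena-cava pressure
  mean_arterial: 93.0            # calibration anchor for the aortic mean

vena_cavae:                      # provenance: literature
  superior: {C_ml_mmHg: 15.0, R_mmHg_s_ml: 0.003, L_mmHg_s2_ml: 5.0e-4}
  inferior: {C_ml_mmHg: 15.0, R_mmHg_s_ml: 0.003, L_mmHg_s2_ml: 5.0e-4}
  abdominal: {C_ml_mmHg: 15.0, R_mmHg_s_ml: 0.003, L_mmHg_s2_ml: 5.0e-4}

heart:                           # provenance: literature
  chambers:
    right_atrium:   {kind: atrium,    E_A_mmHg_ml: 0.06, E_B_mmHg_ml: 0.07,  S_mmHg_s_ml: 5.0e-4}
    right_ventricle: {kind: ventricle, E_A_mmHg_ml: 0.55, E_B_mmHg_ml: 0.045, S_mmHg_s_ml: 5.0e-4}
    left_atrium:    {kind: atrium,    E_A_mmHg_ml: 0.17, E_B_mmHg_ml: 0.15,  S_mmHg_s_ml: 5.0e-4}
    left_ventricle: {kind: ventricle, E_A_mmHg_ml: 2.0,  E_B_mmHg_ml: 0.07,  S_mmHg_s_ml: 5.0e-4}
  timing_fractions:
    atrium:    {T_cs: 0.81, T_cp: 0.10, T_rp: 0.17}
    ventricle: {T_cs: 0.02, T_cp: 0.30, T_rp: 0.15}
  valves:
    tricuspid:       {R_mmHg_s_ml: 0.002, B_mmHg_s2_ml2: 1.0e-5, L_mmHg_s2_ml: 2.0e-4}
    pulmonary_valve: {R_mmHg_s_ml: 0.003, B_mmHg_s2_ml2: 2.0e-5, L_mmHg_s2_ml: 3.0e-4}
    mitral:          {R_mmHg_s_ml: 0.002, B_mmHg_s2_ml2: 1.0e-5, L_mmHg_s2_ml: 2.0e-4}
    aortic:          {R_mmHg_s_ml: 0.003, B_mmHg_s2_ml2: 1.5e-5, L_mmHg_s2_ml: 3.0e-4}

pulmonary:                       # provenance: literature
  compartments:
    pulmonary_artery: {E0_mmHg_ml: 0.092, Phi_ml: 60.0,  S_mmHg_s_ml: 1.0e-4}
    pulmonary_vein:   {E0_mmHg_ml: 0.024, Phi_ml: 150.0, S_mmHg_s_ml: 1.0e-4}
  links:
    pa_to_pv: {R_mmHg_s_ml: 0.07,  L_mmHg_s2_ml: 2.0e-4}
    pv_to_la: {R_mmHg_s_ml: 0.006, L_mmHg_s2_ml: 2.0e-4}

wall:
  poisson_ratio: 0.5             # incompressible wall; provenance: default
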