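# Environmental and surface-exchange defaults for the thermal network.
#
# provenance values as in circuit_defaults.yaml.  The per-segment combined
# (convective + radiative) surface coefficients are editable package
# defaults standing in for manikin-measured values.
schema_version: 1

ambient:
  air_temperature_C: 28.0        # provenance: printed (baseline scenario)
  relative_humidity_pct: 40.0    # provenance: printed (baseline scenario)

# Combined surface heat-transfer coefficient, W/(m^2 K), per segment,
# representative of a supine subject in still air (natural convection
# plus long-wave radiation; extremities slightly higher for curvature).
surface_coefficients_W_m2K:      # provenance: default
  head: 7.0
  neck: 6.5
  chest: 6.4
  abdomen: 6.4
  upper_arm: 6.5
  lower_arm: 6.6
  hand: 7.2
  thigh: 6.4
  leg: 6.6
  foot: 7.2

# Classical thermophysiology respiration-loss formulations:
#   C_res = c_res * M * (T_exhale_ref - T_air)            [W]
#   E_res = e_res * M * (p_ref_kPa - p_air_kPa)           [W]
respiration:                     # provenance: literature
  c_res_W_per_W_K: 0.0014
  exhale_ref_C: 34.0
  e_res_W_per_W_kPa: 0.0173
  vapour_ref_kPa: 5.87

# Insensible skin diffusion: E_sk = w * h_e * A * (p_sat(T_sk) - p_air),
# h_e = lewis_ratio * h_conv, h_conv = h_combined - h_radiative.
skin_evaporation:                # provenance: literature
  wettedness: 0.06
  lewis_ratio_K_kPa: 16.5
  radiative_coeff_W_m2K: 4.7

# In-vessel convective film and vessel-to-tissue conduction coefficients
# used to build the composite conductances TC_ar,I / TC_ve,I / TC_ar,ve.
vessel_films:                    # provenance: default
  film_coeff_W_m2K: 1000.0
  tissue_coeff_W_m2K: 45.0
  av_tissue_coeff_W_m2K: 30.0
  sv_skin_conductance_W_K: 0.5

# Tissue thermal conductivities, W/(m K).
tissue_conductivity_W_mK:        # provenance: literature
  brain: 0.51
  skull: 0.75
  muscle: 0.42
  fat: 0.21
  skin: 0.37
  core: 0.52
  lung: 0.39

# Fraction of limb compartment venous outflow routed through the
# superficial vein (baseline supine neutral: none).
superficial_vein_fraction: 0.0   # provenance: default
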