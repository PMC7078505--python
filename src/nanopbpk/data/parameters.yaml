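# Reference whole-body parameterization for a 200 g rat.
# Values are the package defaults; any field can be overridden from a user
# configuration. Units are stated per field.
version: 1

body:
  body_weight_g: 200.0
  cardiac_output_ml_h: 4217.0
  gfr_ml_h: 78.6            # glomerular filtration rate
  urine_flow_ml_h: 2.0833
  bile_flow_ml_h: 0.9375
  hematocrit: 0.45
  lymph_to_plasma_ratio: 0.002   # lymph flow = plasma flow / 500
  plasma_weight_fraction: 0.0589
  lymph_node_volume_fraction: 0.002  # V_LN = fraction * BW (ml at unit density)

blood:
  viscosity_cP: 4.0
  rbc_radius_um: 3.6

capillary:
  radius_um: 5.0
  length_um: 1000.0
  glycocalyx_nm: 100.0
  velocity_um_s: 553.0      # healthy mean capillary velocity
  shear_rate_per_s: 116.0   # healthy wall shear rate
  capillary_fraction: 0.55  # capillary share of vascular volume

phagocyte:
  motor_power_W: 1.0e-17
  membrane_tension_mN_m: 0.06
  macrophage_radius_um: 15.0
  area_fraction_liver: 0.5
  area_fraction_spleen: 0.1

# per-organ fractions: weight fraction of body, vascular fraction of organ,
# fraction of cardiac output (liver entry is the hepatic-artery share; portal
# inflow from GI and spleen is added at assembly), vessel-wall pore radius.
organs:
  liver:   {f_wt: 0.05,  f_v: 0.21, f_co: 0.021, r_pore_nm: 140.0}
  kidneys: {f_wt: 0.015, f_v: 0.16, f_co: 0.141, r_pore_nm: 4.0}
  lungs:   {f_wt: 0.01,  f_v: 0.36, f_co: 1.0,   r_pore_nm: 2.5}
  spleen:  {f_wt: 0.01,  f_v: 0.22, f_co: 0.02,  r_pore_nm: 2500.0}
  brain:   {f_wt: 0.03,  f_v: 0.04, f_co: 0.02,  r_pore_nm: 0.5}
  heart:   {f_wt: 0.01,  f_v: 0.26, f_co: 0.051, r_pore_nm: 2.5}
  gi:      {f_wt: 0.04,  f_v: 0.2,  f_co: 0.133, r_pore_nm: 2.5}
  muscle:  {f_wt: 0.3,   f_v: 0.04, f_co: 0.278, r_pore_nm: 2.5}
  others:  {f_wt: 0.03,  f_v: 0.01, f_co: 0.01,  r_pore_nm: 2.5}

tumor:
  radius_mm: 5.0
  specific_blood_flow_ml_g_min: 0.1
  viscosity_cP: 7.42
  vascular_fraction: 0.1
  pore_radius_nm: 850.0
  porosity: 0.001
  wall_thickness_um: 5.0

nanoparticle:
  radius_nm: 50.0        # reference size 100 nm (diameter)
  density_g_cm3: 2.0
  k_deg_per_h: 0.01

constants:
  k_B: 1.38e-23
  T_K: 310.0
  g_m_s2: 9.8
  rho_plasma_g_cm3: 1.0
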