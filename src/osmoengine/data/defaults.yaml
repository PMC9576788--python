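# Default model parameters.
#
# Units: lengths um, areas um^2, concentrations mM (= attomol/um^3),
# pressures Pa, time s, potentials mV, amounts attomol.
#
# Every value marked "placeholder" is a physiologically motivated choice made
# once for this implementation (the source model's own parameter table is not
# reproduced here); see docs/methods.md for the rationale behind each group.

cell_length: 50.0          # um, confined cell in a microchannel (placeholder)
cross_section: 30.0        # um^2, 3 um x 10 um channel (placeholder)

# --- actin / mechanics ---
interfacial_friction: 10.0     # Pa s / (mM um^2), cytosol-network drag (placeholder)
adhesion_strength: 100.0       # Pa s / (mM um^2), focal-adhesion body force (placeholder)
wall_friction: 2.0e+4           # Pa s / um, channel-wall friction on the whole cell (placeholder)
depolymerization_rate: 0.002   # 1/s (placeholder)
gactin_diffusivity: 13.0       # um^2/s, G-actin monomer (placeholder)
actin_stiffness: 1000.0        # Pa/mM, network swelling stress per F-actin concentration (placeholder)
mean_actin: 0.5                # mM, domain-average F+G actin (placeholder)
polymerization_saturation: 0.2 # mM, half-saturation of front polymerization (placeholder)
membrane_thickness_factor: 0.1 # um, prefactor b of the membrane force balance (placeholder)

# --- thermodynamic constants ---
gas_constant: 8.314        # J/(mol K); RT*c(mM) is then in Pa
temperature: 310.0         # K
faraday: 96485.0           # C/mol

# --- CO2 / buffer chemistry ---
henry_constant: 20.98      # mmHg/mM: P_CO2/k_H ~ 1.9 mM dissolved CO2 (placeholder)
pco2: 40.0                 # mmHg (placeholder)
pk_c: 6.3                  # carbonic acid effective pK
pk_b: 7.0                  # intracellular buffer pK (placeholder)

# --- extracellular environment (shared by both ends unless overridden) ---
extracellular_ph: 7.4
extracellular_potential: 0.0   # mV reference
external:
  na: 140.0                # mM (placeholder)
  k: 5.0                   # mM (placeholder)
  cl: 110.0                # mM (placeholder)
  a: 11.0                  # mM, impermeant extracellular solute; balances medium osmolarity (placeholder)
  g: 0.0                   # extracellular G-actin: fixed 0, non-exchanging

# --- impermeant intracellular species ---
impermeant_total: 1.0e+5    # attomol N_A over the 1500 um^3 cell (~67 mM average) (placeholder)
buffer_total: 6.2e+4        # attomol N_Buf + N_HBuf (~41 mM average) (placeholder)
impermeant_valence: -1.0   # z_A, average protein charge (configurable)
buffer_valence: -1.0       # z_Buf

# --- cytoplasmic diffusivities, um^2/s (placeholder values ~half of dilute water) ---
diffusivity:
  na: 600.0
  k: 700.0
  cl: 700.0
  h: 3000.0
  hco3: 500.0
  a: 10.0
  buf: 500.0
  hbuf: 500.0

# --- gating constants ---
gating:
  beta1: 0.002   # 1/(Pa um): mechanosensitive gate sharpness (placeholder)
  beta2: 1300.0  # Pa um: mechanosensitive gate midpoint tension (placeholder)
  beta3: 0.02    # 1/mV: pump voltage-gate sharpness (placeholder)
  beta4: -150.0  # mV: pump voltage-gate midpoint (placeholder)
  beta5: 4.0     # NHE pH-gate sharpness; quiescent above pH ~7.2
  beta6: 7.2     # NHE pH-gate midpoint
  beta7: 4.0     # AE2 pH-gate sharpness; quiescent below pH ~7
  beta8: 7.1     # AE2 pH-gate midpoint (placeholder)
  clamp_gm: null # diagnostic: force G_m to this value when set (e.g. 1.0)

# --- Na+/K+ pump saturation scalings ---
nke:
  beta_na: 0.08  # scales Gamma_Na in the cubic Hill factor (placeholder)
  beta_k: 0.034  # scales 1/Gamma_K in the quadratic Hill factor (placeholder)

# --- per-end membrane parameters ---
# Flux units: water um/s; ion fluxes mM um/s; passive alphas are pre-scaled so
# alpha * [RT ln Gamma - z F V_m] is in mM um/s.
# Baseline polarization: SWELL1 (passive Cl-) enriched at the rear
# (alpha_cl back/front = 4) and NHE enriched at the front (front/back = 1.1),
# holding geometric means fixed.
front:
  water_permeability: 1.2e-4   # um/(s Pa) (placeholder)
  hydraulic_resistance: 1.0e+5  # Pa s/um, channel hydraulic resistance (placeholder)
  external_pressure: 0.0       # Pa
  alpha_na: 2.0e-5             # passive Na+ leak (placeholder)
  alpha_k: 1.5e-3              # passive K+ (placeholder)
  alpha_cl: 5.0e-5             # passive Cl- = SWELL1 pathway, front (placeholder)
  alpha_nke: 3.0               # Na/K pump strength, mM um/s at saturation (placeholder)
  alpha_nhe: 2.098e-3          # NHE, front-enriched (placeholder)
  alpha_ae2: 3.0e-3            # AE2 (placeholder)
  j_actin: 0.0015              # mM um/s, front polymerization rate scale (placeholder)
back:
  water_permeability: 1.2e-4
  hydraulic_resistance: 1.0e+5
  external_pressure: 0.0
  alpha_na: 2.0e-5
  alpha_k: 1.5e-3
  alpha_cl: 2.0e-4             # SWELL1 pathway, rear-enriched (placeholder)
  alpha_nke: 3.0
  alpha_nhe: 1.907e-3
  alpha_ae2: 3.0e-3
  j_actin: 0.0                 # actin flux is zero at the back of the cell

# --- model-form switches ---
advection: frame        # 'frame': bulk advection uses v - v0 (moving frame); 'lab': printed lab velocities
force_balance: printed  # 'printed': hydraulic term uses front water flux only; 'symmetrized': both ends
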