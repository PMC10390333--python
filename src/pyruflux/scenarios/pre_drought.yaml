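# Pre-drought labelling campaign: 3 sites x 3 replicate C1/C2 chamber pairs,
# 100 mg sodium [13C]pyruvate per collar, ~64 closures over 48 h.
# Allocation truths encode the pre-drought partition of the injected 13C
# (41.0% biosynthesis / 21.1% TCA / 37.9% other); VOC yields are expressed
# as fractions of the biosynthesis 13C pool emitted from C2 chambers and
# jointly encode the pre-drought VOC share of biosynthesis (0.0040%).
condition: pre_drought
n_sites: 3
replicates_per_site: 3
label_positions: [C1, C2]
injected_pyruvate_mass_mg: 100.0
pyruvate_molar_mass_g_mol: 111.03
labelled_positions_per_molecule: 1
collar_area_m2: 0.0318
chamber_volume_m3: 0.004076
air_temperature_k: 296.15
air_pressure_pa: 101325.0
baseline_co2_flux: 4.0
baseline_delta13c: -25.0
allocation_truth:
  f_bio: 0.410
  f_tca: 0.211
  f_other: 0.379
voc_truth:
  acetate:
    formula: C2H4O2
    carbon_count: 2
    f_voc_of_bio: 1.294595465778446e-05
    c1_acetogenesis_frac: 1.0e-05
    tau_h: 6.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.10
    baseline_conc_nmol_mol: 1.0
  acetone:
    formula: C3H6O
    carbon_count: 3
    f_voc_of_bio: 2.305404534221554e-05
    tau_h: 8.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.05
    baseline_conc_nmol_mol: 2.0
  diacetyl:
    formula: C4H6O2
    carbon_count: 4
    f_voc_of_bio: 4.0e-06
    tau_h: 8.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.02
    baseline_conc_nmol_mol: 0.2
pulse_shape: 1.0
pulse_tau_h: 5.0
chamber_scale_sd: 0.08
baseline_scale_sd: 0.10
closure_curvature_per_s: 5.0e-05
pre_injection_hours: 12.0
pre_spacing_h: 2.0
fast_until_h: 8.0
fast_spacing_h: 0.5
slow_spacing_h: 0.8333333333333334
end_h: 48.0
closure_length_s: 390.0
closure_cadence_s: 2.0
voc_cadence_s: 10.0
voc_length_s: 150.0
sigma_x12_umol_mol: 0.05
sigma_x13_umol_mol: 0.005
sigma_voc_nmol_mol: 0.02
soil_moisture_mean_pct: 26.0
soil_moisture_sd_pct: 6.9
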