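# Drought labelling campaign.  Allocation truths encode the drought
# partition (17.3% biosynthesis / 11.1% TCA / 71.6% other); relative to the
# pre-drought scenario these imply cumulative 13C-CO2 decreases of 54.3%
# (C1 chambers) and 47.4% (C2).  VOC yields jointly encode the drought VOC
# share of biosynthesis (0.15%) and the cumulative-efflux factors versus
# pre-drought: acetate-C2 x2.6, acetone-C2 x25.3, acetate-C1 x1.9
# (acetogenesis), diacetyl x4.  Baseline soil respiration is reduced and
# soil moisture low; the label pulse relaxes more slowly (tau 7 h).
condition: drought
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
baseline_co2_flux: 1.8
baseline_delta13c: -25.0
allocation_truth:
  f_bio: 0.173
  f_tca: 0.111
  f_other: 0.716
voc_truth:
  acetate:
    formula: C2H4O2
    carbon_count: 2
    f_voc_of_bio: 7.977102696646378e-05
    c1_acetogenesis_frac: 1.9e-05
    tau_h: 6.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.15
    baseline_conc_nmol_mol: 1.0
  acetone:
    formula: C3H6O
    carbon_count: 3
    f_voc_of_bio: 1.3823098978890276e-03
    tau_h: 8.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.10
    baseline_conc_nmol_mol: 2.0
  diacetyl:
    formula: C4H6O2
    carbon_count: 4
    f_voc_of_bio: 3.7919075144508665e-05
    tau_h: 8.0
    shape: 1.0
    baseline_flux_nmol_m2_s: 0.03
    baseline_conc_nmol_mol: 0.2
pulse_shape: 1.0
pulse_tau_h: 7.0
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
soil_moisture_mean_pct: 13.8
soil_moisture_sd_pct: 2.6
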