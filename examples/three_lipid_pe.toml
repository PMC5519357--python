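# Matching phosphatidylethanolamine trio at 30 °C: smaller head group
# (smaller per-lipid area, slightly thicker bilayer), same acyl-chain
# ordering — the di-DHA species again has the smallest K_A and thickness.

[run]
output_dir = "results_pe"
d0_nm = 1.0
bin_width_nm = 0.05
equilibration_fraction = 0.25

[lipids.DOPE]
temperature_C = 30
[lipids.DOPE.synthetic]
area_modulus_mn_per_m = 270.0
reference_area_nm2 = 122.0
thickness_nm = 3.80
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 21

[lipids.DAPE]
temperature_C = 30
[lipids.DAPE.synthetic]
area_modulus_mn_per_m = 255.0
reference_area_nm2 = 128.0
thickness_nm = 3.65
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 22

[lipids.DDPE]
temperature_C = 30
[lipids.DDPE.synthetic]
area_modulus_mn_per_m = 235.0
reference_area_nm2 = 133.0
thickness_nm = 3.40
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 23
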