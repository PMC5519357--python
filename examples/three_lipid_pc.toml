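# Three-PC comparison at 30 °C: di-oleoyl (18:1), di-arachidonoyl (20:4)
# and di-DHA (22:6) phosphatidylcholine bilayers, 400 lipids each.
# Ground-truth K_A and d are realistic all-atom values; the di-DHA species
# is the softest and thinnest, so its bending rigidity comes out lowest.

[run]
output_dir = "results_pc"
d0_nm = 1.0
bin_width_nm = 0.05
equilibration_fraction = 0.25

[lipids.DOPC]
temperature_C = 30
[lipids.DOPC.synthetic]
area_modulus_mn_per_m = 265.0
reference_area_nm2 = 135.0
thickness_nm = 3.70
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 11

[lipids.DAPC]
temperature_C = 30
[lipids.DAPC.synthetic]
area_modulus_mn_per_m = 250.0
reference_area_nm2 = 140.0
thickness_nm = 3.60
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 12

[lipids.DDPC]
temperature_C = 30
[lipids.DDPC.synthetic]
area_modulus_mn_per_m = 230.0
reference_area_nm2 = 145.0
thickness_nm = 3.35
peak_sigma_nm = 0.35
n_frames = 20000
n_phosphorus = 400
correlation_rho = 0.0
seed = 13
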