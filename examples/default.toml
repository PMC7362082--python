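[parameters]
k1 = 1.5
k2 = 0.0003
d2 = 46.0
k3 = 130.0
d3 = 10.0
k4 = 13.0
d4 = 20.0
k5 = 0.1
k6 = 0.0002
d5 = 11.5

[fiber]
length_nm = 12000.0
diameter_nm = 330.0
protein_fraction = 0.3
monomer_radius_nm = 2.25
element_rest_length_nm = 46.0

[clot]
diameter_mm = 2.0
fiber_density_per_um3 = 0.5
fiber_length_um = 12.0

[simulation]
force_max_pn = 200.0
n_steps = 500
solver_tolerance_pn = 1e-08
random_seed = 0
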