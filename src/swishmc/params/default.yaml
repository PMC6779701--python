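helix_center:
- -57.0
- -47.0
helix_width: 20.0
helix_depth: 2.5
extended_center:
- -135.0
- 135.0
extended_width: 25.0
extended_depth: 1.6
eps_ca: 0.2
sigma_ca: 4.4
eps_c: 0.05
sigma_c: 3.6
eps_sc_h: 0.3
eps_sc_p: 0.12
sigma_sc: 4.5
eps_no: 0.05
sigma_no: 2.8
hard_core: 1.2
dielectric: 78.5
debye_length: 9.6
coulomb_k: 332.0636
coulomb_saturation: 6.0
dispersion_s: -0.08
neighbor_cutoff: 6.5
n_max: 10
temperature: 300.0
delta_max: 25.0
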