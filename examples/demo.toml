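# Demo pipeline configuration: a heterogeneous two-population ensemble
# (rigid helix core + mobile terminus) analyzed under three excitation
# conditions (CP 20 us, CP 700 us, direct).

[physics]
r_eff_angstrom = 1.117
kappa = 0.5773502691896258

[mas]
nu_r = 5000.0
n_points = 9

[fit]
scan_step = 0.01
uncertainty = "jackknife"

[run]
seed = 1
output_dir = "scratch/demo"

[ensemble]
noise_sd = 0.0
populations = [
    { S = 0.85, weight = 0.5, label = "rigid-helix" },
    { S = 0.17, weight = 0.5, label = "mobile-terminus" },
]
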