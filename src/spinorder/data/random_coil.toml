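# Random-coil Calpha/Cbeta reference shifts (ppm) from standard published
# random-coil compilations (Wishart-type tables). Editable: replace with a
# lab-calibrated table if desired.

[Met]
ca = 55.4
cb = 32.9

[Arg]
ca = 56.1
cb = 30.3

[His]
ca = 55.4
cb = 29.1
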