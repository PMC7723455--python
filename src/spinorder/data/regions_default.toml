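# Calpha chemical-shift analysis windows (ppm) per labelled residue type.
# "helix" and "coil" are [lo, hi] windows; "sheet" is an open-ended upper
# cutoff (everything strictly below is attributed to aggregated protein).
# The gap between the Arg sheet cutoff (53.3) and coil window (54.0) is
# deliberate and classifies as unassigned.

[Met]
helix = [55.0, 59.2]
coil = [52.7, 54.8]
sheet = 52.7

[Arg]
helix = [56.7, 60.2]
coil = [54.0, 56.6]
sheet = 53.3

[His]
helix = [56.0, 58.8]
coil = [52.5, 56.0]
sheet = 52.5
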