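# spinorder

Solid-state NMR toolkit for quantifying the segmental dynamics of
membrane proteins — G-protein-coupled receptors in particular — from
magic-angle-spinning (MAS) experiments on residue-type ¹³C-labelled
samples reconstituted in lipid bilayers.

The package covers the three quantitative stages of such a study:

1. **DIPSHIFT order parameters.** Separated-local-field (DIPSHIFT)
   experiments measure motionally averaged ¹H–¹³C dipolar couplings. The
   package simulates dipolar dephasing curves over one rotor period under
   MAS with powder averaging, fits experimental curves by least squares
   against those simulations, and converts the result to the molecular
   order parameter

   *S* = *D*<sub>exp</sub> / *D*<sub>rigid</sub>,

   which runs from 0 (isotropic mobility) to 1 (complete rigidity). The
   rigid limit is computed from the point-dipole expression at an
   effective bond length (default 1.117 Å → ≈ 21.7 kHz), and the
   frequency-switched Lee–Goldburg (FSLG) homonuclear decoupling applied
   during evolution scales the coupling by κ = 1/√3; both conventions are
   explicit configuration, not hidden constants.

2. **Chemical-shift region quantification.** Without site resolution,
   Cα intensity is classified by fixed ppm windows per residue type
   (α-helix, random coil, and a β-sheet cutoff capturing aggregated
   protein), or per cross peak from the Cα–Cβ secondary-shift difference
   against random-coil references. 1D windows and 2D cross-peak boxes are
   integrated trapezoidally and reported as class fractions.

3. **³¹P lineshapes.** Static ³¹P spectra of the lipid bilayer are
   modelled as an axially symmetric CSA powder pattern plus a narrow
   isotropic line; a two-component least-squares decomposition estimates
   the isotropic signal fraction (small vesicles/micelles vs lamellar
   bilayer).

A synthetic-data module generates dephasing curves (including the
dynamic bias of cross-polarization toward rigid sites as a function of
contact time), Gaussian-peak 1D/2D spectra, and two-component ³¹P
spectra, so the entire chain is testable end to end without measured
data.

## Worked example

Simulate a noise-free dephasing curve for a rigid helical site
(*S* = 0.85, the kind of value a 20 µs CP contact selects for) at 5 kHz
MAS and fit it back:

```sh
$ spinorder simulate --s 0.85 --out curve.tsv
wrote curve.tsv
$ spinorder fit --curve curve.tsv --out fit.json
S = 0.850 +/- 0.000 (jackknife); wrote fit.json
```

The fitted order parameter reproduces the input to the scan resolution;
the JSON report carries the full physics provenance (κ, rigid-limit
coupling, grid, powder scheme).

The demo pipeline analyzes a heterogeneous two-population ensemble
(rigid helix core *S* = 0.85 + mobile terminus *S* = 0.17, equal
weights) under three excitation conditions:

```sh
$ spinorder run --config examples/demo.toml
ensemble [cp 20 us]: S = 0.825 +/- 0.001
ensemble [cp 700 us]: S = 0.755 +/- 0.004
ensemble [direct]: S = 0.552 +/- 0.006
```

The ordering is the physics of CP bias: a 20 µs contact polarizes almost
exclusively the rigid half of the ensemble (apparent S close to 0.85), a
700 µs contact mixes in mobile sites, and direct excitation weights all
sites equally, pulling the apparent order parameter down toward the
ensemble average.

In Python the same chain is three calls:

```python
from spinorder import (MASCondition, one_bond_ch, fslg,
                       dephasing_curve, fit_dephasing)

pair, scale = one_bond_ch(), fslg()
mas = MASCondition.evenly_spaced(5000.0, 9)
curve = dephasing_curve(scale.kappa * 0.85 * pair.d_rigid, mas)
fit = fit_dephasing(curve, pair, scale)
print(fit.S_fit)   # 0.85
```

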