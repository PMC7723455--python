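# Methods

This note documents the models implemented in `spinorder`, the defaults
and why they were chosen, and what the synthetic-data generator does and
does not emulate.

## Dipolar physics and the order-parameter convention

A ¹H–¹³C spin pair couples through the point-dipole interaction; the
rigid-limit coupling constant in Hz is

    D_rigid = (mu0 / 8 pi^2) * gamma_H * gamma_C * hbar / r_eff^3.

With the default vibrationally averaged one-bond distance
r_eff = 1.117 Å this gives 21.68 kHz. Published conventions for the
one-bond rigid limit span roughly 21.5–23.3 kHz depending on how
vibrational averaging is treated, and reported order parameters inherit
that convention; `spinorder` therefore exposes `r_eff` and an explicit
`d_rigid_hz` override in configuration and logs which one is in force,
rather than resolving the convention silently. All couplings are carried
in Hz; 2π enters only inside phase evaluation, so there is a single
unit-conversion point.

Homonuclear ¹H decoupling during the dipolar evolution period scales the
heteronuclear coupling. The default scale factor is the theoretical
Lee–Goldburg value κ = 1/√3 ≈ 0.5774; experimentally calibrated values
drift by a few percent and can be substituted in config. The coupling
that evolves is d_eff = κ·S·D_rigid, and the fitted d_eff is divided by
κ·D_rigid to report S.

## DIPSHIFT simulation

For a crystallite at powder angles (β, γ) the MAS-modulated heteronuclear
frequency is

    omega(t) = 2 pi d_eff [ (sqrt2/2) sin(2 beta) cos(w_r t + gamma)
                           - (1/2) sin^2(beta) cos(2 w_r t + 2 gamma) ],

whose time integral (the dephasing phase) is available in closed form.
Both terms are pure rotor harmonics, so the phase vanishes at t₁ = τ_r
for every orientation — the full-rotor refocusing that anchors the
normalization of every curve. The observed curve is the powder average
of cos Φ(t₁).

Numerical choices:

- **Powder scheme.** A deterministic midpoint grid, 128 β × 64 γ with
  sin β weights (8192 orientations), chosen for bit-reproducibility over
  Monte-Carlo orientation sampling. An automatic convergence check
  (doubling both grid dimensions, warning above 1e-4 pointwise change)
  is available; the default grid passes it across the coupling range of
  interest (d_eff up to ~2 ν_r). The scheme is pluggable.
- **t₁ grid.** Nine equally spaced delays spanning [0, τ_r] inclusive by
  default, seven selectable — both endpoint-inclusive so the refocusing
  point is part of every curve. Whether a measured grid includes both
  endpoints is an acquisition choice; the grid is fully configurable and
  file-driven grids are used as given.
- **One effective pair.** Each spectral region is modelled as a single
  effective I–S coupling; CH₂/CH₃ multiplicity and remote protons are
  folded into d_eff. This matches a single-coupling fit per region and
  is the resolution the data support without site assignment.
- **Ideal sequence.** Pulse imperfections and finite-pulse effects are
  not simulated; echo-refocused chemical-shift evolution and T₂ decay
  during t₁ are likewise outside the model (sequence variants designed
  to suppress dephasing-curve distortions are approximated by the same
  ideal curve). The rotor phase origin is immaterial after γ averaging,
  which a property test asserts.

Since the phase is linear in d_eff, a single "unit phase" array per
(grid, scheme) serves every coupling; it is cached, which makes
scan-based fitting and Monte-Carlo replication cheap.

## Fitting

The fitter minimizes Σ [I_obs − A·I_sim(S)]² over S ∈ [0, 1] using the
same simulation engine as the forward model, so noise-free recovery is
limited only by scan resolution. A coarse global scan (step 0.01 in S)
precedes bounded local refinement; the scan guards against the local
minima oscillatory curves develop once d_eff approaches the rotor
frequency. The amplitude A absorbs integration/normalization error and
is bounded in [0.9, 1.1] so it cannot trade against S; a pure-shape fit
(A ≡ 1) is selectable. No baseline offset is fitted by default because
the experiment refocuses to full intensity; an offset can be enabled for
degraded data by pre-processing. A best fit at the S = 1 boundary raises
a warning (escalatable to an error): it usually means the rigid-limit
convention is off, not that the site is super-rigid.

**Uncertainty.** The default is a delete-one jackknife over t₁ points
(the t₁ = 0 anchor always kept), which requires ≥ 6 points and is
reported as such alongside the value. Alternatives: Monte-Carlo over
replicate noisy curves (via the generator) and local curvature of the
objective. The method label always travels with σ_S because resampling
units differ between labs and none is canonical.

## Chemical-shift regions

Per-residue Cα windows map shift to secondary structure: for Met
55.0–59.2 ppm helix, 52.7–54.8 ppm coil, < 52.7 ppm sheet; for Arg
56.7–60.2 / 54.0–56.6 / < 53.3 ppm; for His 56–58.8 / 52.5–56 /
< 52.5 ppm. Sheet-class intensity in these samples reports aggregated
(misfolded) protein, spectrally separated from the functional receptor.
Two conventions are fixed deliberately:

- A shift exactly on a printed boundary shared by two windows belongs to
  the **higher-ppm** window (helix and coil windows are closed intervals
  checked in descending-ppm order; the sheet region is strictly below
  its cutoff).
- Gaps between printed windows — Arg 53.3–54.0 ppm is such a gap —
  classify as `unassigned`, never silently merged into a neighbour.

The Δδ(Cα) − Δδ(Cβ) secondary-shift classifier uses shipped random-coil
reference shifts (standard published compilations; the TOML is editable)
and symmetric ±1.4 ppm thresholds by default, configurable — the
threshold is explicit config, not a hidden constant. Integration is
trapezoidal with interpolated window edges (1D) and double-trapezoid
boxes with a pairwise-disjointness check (2D); class fractions are
normalized to sum to one.

## ³¹P lineshape

For fast axial motion (η = 0) the resonance offset is
ν(θ) = δ_iso + (Δσ/2)(3 cos²θ − 1). With u = cos θ uniform on [0, 1],
the intensity between two ppm grid edges is the difference of u at the
edges — the lineshape is computed through this orientation CDF, which is
exact per cell and handles the perpendicular-edge singularity without
special-casing — then convolved with a Lorentzian (default; matches
exponential apodization) or Gaussian kernel. A zero-anisotropy component
is sampled from the kernel directly rather than binned as a point mass,
which would be hypersensitive to sub-cell axis shifts. The sign
convention is Δσ = σ∥ − σ⊥ of the motionally averaged tensor; bilayer
patterns have the intense edge on the high-field side with the default
negative Δσ, and the sign is config-flippable since conventions differ.

The isotropic fraction is estimated by a two-component least-squares
decomposition: non-negative amplitudes of unit-area powder and isotropic
basis shapes (NNLS), with optional bounded refinement of Δσ and the two
widths around the initial model. Because the basis shapes have unit
area, the amplitude ratio is the area ratio directly. A window-
integration mode is provided as a labelled cross-check; it is biased by
powder intensity under the window and the two modes are never conflated
in output.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Ensembles.** A region is a weighted mixture of sub-populations with
  distinct true order parameters; the observed curve is the weighted sum
  of single-site curves, renormalized at t₁ = 0.
- **CP bias.** Excitation weights follow classical I–S cross-polarization
  thermodynamics, w = exp(−t_cp/T1ρ)·(1 − exp(−t_cp·S^p/T_IS0)) with
  p = 2 (buildup rate proportional to the squared effective coupling)
  and defaults T_IS0 = 100 µs, T1ρ = 5 ms. These constants make a 20 µs
  contact polarize rigid sites (S > 0.6) more than 5× as efficiently as
  mobile ones (S < 0.3) — a declared generative model that realizes the
  qualitative rigidity bias of CP quantitatively, not a claim about the
  true spin physics. Direct excitation is w ≡ 1 for all sites. T1ρ is
  site-independent in this model, so it cancels after normalization; a
  mobility-dependent T1ρ would add a second bias channel not modelled
  here.
- **Noise.** Additive i.i.d. Gaussian noise on normalized intensities,
  default sd 0.02 (the integral signal-to-noise regime of a few mg of
  labelled receptor); the t₁ = 0 point is noisy like any other.
- **Spectra.** 1D/2D sums of Gaussians parameterized by analytic
  area/volume, so integration round-trips have exact targets. Two-
  component ³¹P spectra come from the same forward model the fitter
  uses.

All generators draw from `numpy.random.default_rng(seed)`; equal seeds
give bit-identical outputs.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: lineshape distortions (phase
roll, t₁-noise ridges), baseline errors, lipid background signals,
correlated noise between t₁ points, mobility-dependent T1ρ, and
multi-spin effects. Recovery statistics measured on synthetic data are
statements about the estimator under the declared noise model, not
about spectrometer data.

## Problem sizes

Default analyses use the 128 × 64 powder grid, 9-point t₁ grids, a
0.01 scan step, 2048-point ³¹P axes, and ~400-point-per-axis synthetic
2D spectra; the Monte-Carlo recovery suite runs 100 replicates per order
parameter over the fifteen-value grid. These sizes put every quantity
well inside its tolerance (powder convergence < 1e-4, integration error
< 1 %) while keeping the full test suite in the tens of seconds on one
core.

## Known limitations

- Only amplitude information is extracted: DIPSHIFT-type experiments at
  these conditions sample all motions faster than a few tens of µs, and
  no correlation times are fitted.
- The rigid-limit and κ conventions are exposed, not resolved; order
  parameters are only comparable between datasets that share them.
- η ≠ 0 CSA tensors are not simulated (bilayer-averaged ³¹P tensors are
  axially symmetric; fitting η to such data is ill-posed).
- No peak picking, assignment, or lineshape deconvolution of overlapped
  Cα signals; region analysis is window-based by design.
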