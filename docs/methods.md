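# Methods

This note records the models implemented in `lipidorder`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user extending the package should know about.

## Spectral model

A Laurdan emission spectrum is modelled as the sum of two elementary bands:
a *blue* band from probe molecules in a rigid, dehydrated lipid environment
and a *green* band from molecules in a fluid, hydrated one. Each band is an
asymmetric log-normal in wavelength,

    I(λ) = A · exp[ −(ln 2 / ln²ρ) · ln²(1 + (λ − λ_max)(ρ² − 1)/(ρ w)) ]

with amplitude `A` (counts), mode `λ_max` (nm), full width at half maximum
`w` (nm) and asymmetry `ρ > 1` defined as the red-side over blue-side
half-width at half maximum. The band is identically zero at and below its
finite blue-side cutoff `λ_max − ρw/(ρ² − 1)` and tails to the red, as
electronic emission bands do on a wavelength axis. The band area has the
closed form `A·(ρw/(ρ²−1))·ln ρ·√(π/ln 2)·exp(ln²ρ/(4 ln 2))`, verified
against quadrature in the tests; relative areas therefore never depend on
an integration grid.

Derived quantities:

* `S_b = area(blue)/(area(blue) + area(green))`, `S_g = 1 − S_b`. The
  normalisation is against the sum of the two fitted bands, not the raw
  spectrum integral; the ratio fitted-total/raw-total is reported separately
  (`area_ratio`) as a fit diagnostic.
* `ΔS_r = S_b − S_g` (higher = more ordered), `R_S = S_g/S_b` (higher =
  more fluid), linked by the identity `R_S = (1 − ΔS_r)/(1 + ΔS_r)`.
  `R_S` is oriented green-over-blue: only this orientation makes a strongly
  ordered membrane (`S_b = 0.82`) give a small ratio (0.22) and a fluid one
  (`ΔS_r = −0.55`) a large ratio (3.4).
* `GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀)` from point interpolation at exactly
  440.0/490.0 nm, not band integrals — GP is conventionally defined on
  measured intensities at those two wavelengths.

## Fitting

`fit_two_lognormal` is a bounded trust-region least-squares fit (lmfit /
`least_squares`) of the blue + green sum. Defaults:

* position bounds 425–470 nm (blue) and 480–530 nm (green), wide enough for
  liposome spectra (~438–444 / ~494–500 nm) and the red-shifted, broader
  bands of cell membranes (~451–462 / ~506–520 nm);
* FWHM bounds 15–120 nm; initialisation at 440/490 nm, width 45 nm,
  amplitudes read off the spectrum at the initial positions;
* convergence: relative tolerance 1e-8 or 2000 evaluations; deterministic
  restart ladder of ±10 nm position offsets if the first attempt reports
  failure. There is no randomness anywhere in the fit, so identical input
  and configuration give identical results.

**Asymmetry handling.** `FitConfig.asymmetry` is `"fixed"` (default),
`"shared"` or `"free"`. The default treats `ρ` as a known constant of the
probe's emission band (1.35) rather than a free parameter, for an
identifiability reason that is easy to state: the blue and green bands
overlap over most of their support, and a local-information (Cramér–Rao)
analysis at realistic conditions — 1-nm sampling over 400–600 nm, noise 2%
of the peak (SNR 50) — gives a standard deviation of 0.02–0.03 on `S_b`
and up to ~1.8 nm on a weak band's position when each band's asymmetry is
free. With `ρ` held fixed the same analysis gives ~0.006 on `S_b` and
~0.3 nm on positions, which the measured recovery statistics reproduce.
A mis-specified fixed `ρ` biases `S_b` (about −0.03 for `ρ` mis-set by
0.05), so when the probe constant is in doubt the `"shared"` mode — one
common fitted asymmetry — is the conservative alternative at roughly double
the `S_b` uncertainty.

Preconditions: the spectrum must be corrected and nonnegative (clip after
blank subtraction), at least 20 samples, and must cover 430–540 nm so that
both GP wavelengths and all admissible band modes are inside the data.
An all-zero spectrum is a degenerate-input error, not a fit result.

## Spectrum corrections

`correct_spectrum` applies `max(0, (s − blank) · response)`: the blank
(probe-free sample capturing Raman scattering of water near 433 nm for
378 nm excitation, plus elastic scatter) is subtracted first, then the
multiplicative instrument-response curve is applied — scattering artifacts
are recorded through the same detector and share its spectral sensitivity.
The opposite order is available (`order="multiply_then_subtract"`) for
blanks that were already response-corrected; with a shared grid the two
differ only by which correction the blank has seen. Negative residuals
after subtraction are blank noise and are clipped to zero with a logged
warning, because the band fit requires nonnegative data. All resampling is
linear: spectra sampled at 1 nm are smooth on that scale and higher-order
interpolation adds ringing near the steep blue band edge without reducing
the error (the down/upsample round-trip error at 1-nm resolution is below
1% of the peak).

## Dose–response analysis

A titration of one membrane system is assembled into a concentration-indexed
table (`build_series`; the 0 µM control is mandatory) and differenced
against the control (`compute_deltas`). Parameter *sensitivity* across
systems is operationalised — there is no canonical definition — as a
separation score: for each parameter, the minimum over system pairs of the
mean absolute difference between their delta curves, normalised by the
parameter's pooled delta range. The score is large only when every pair of
systems stays distinguishable along the whole titration; uniform rescaling
of a parameter cancels out, so the ranking reflects divergence between
systems, not units. With a single system the score is undefined and only
the per-parameter maximum |delta| table is returned. Replicates are
supported as mean ± SD aggregation only; no hypothesis testing is applied
to deltas, and no error propagation from the control subtraction.

## Bilayer snapshot analysis

Frames hold lipid phosphate heads, the four glycerol-backbone reference
atoms O21/C22/O31/C31 per lipid, water oxygens and optional channel atoms
in an orthorhombic periodic box, in nm (PDB input in Å is converted;
PDB/GRO parsing is delegated to MDAnalysis).

* **Leaflets**: by head z against the mean head z; `z ≥ mean` is upper
  (the documented tie rule). Coplanar heads are a degenerate error.
* **Grid APL**: an `Nx×Ny` lateral grid (default 100×100); each cell goes
  to the head minimising the minimum-image lateral distance to the cell
  centre, exact ties to the lowest lipid id (determinism). The tessellation
  partitions the box, so per-leaflet areas sum to `Lx·Ly` exactly and the
  leaflet mean APL is exactly `Lx·Ly/n` at any resolution. Per-lipid areas
  converge to the periodic Voronoi areas as the grid refines; the
  discretisation error of a single lipid's area is of order
  (cell side) × (its Voronoi-cell perimeter) — *not* one cell area — with
  random sign, which matters when quoting per-lipid rather than group
  values. Channel atoms do not claim cells by default (the scheme assigns
  cells to lipid heads only, so the pore area is shared by the first lipid
  shell); `include_peptide=True` lets them compete and reports the area
  they claim separately.
* **Near-channel split**: a lipid is near the channel when the minimal
  periodic lateral distance from its head to any channel atom is ≤ 0.3 nm —
  a first-shell criterion. A literal shell around the channel's centre of
  mass (a point inside the pore) selects almost nothing at that cutoff, so
  the atom-referenced shell is the default and the COM reference is an
  option (`reference="com"`).
* **Water insertion**: per lipid, the centre of its four reference atoms
  (unit masses by default; atomic masses shift the centre by well under
  0.02 nm, below the method's resolution); distinct water oxygens within a
  3D periodic cutoff (default 0.3 nm) of any centre are counted, each water
  once. The production path uses a periodic k-d tree and is tested equal to
  the brute-force all-pairs count. Oxygen positions, not hydrogens, define
  the water location.
* **Ensembles**: `frame_statistics` evaluates both leaflets, near/bulk
  groups and water counts per frame and aggregates mean ± SD (ddof = 1).

## Synthetic generators

The generators produce data with the statistical structure the analysis
assumes, plus a truth record, so tests compare against construction.

**Spectra.** Blue + green bands on a 1-nm 400–600 nm grid; the target `S_b`
is planted by scaling amplitudes at fixed band shapes. Default bands are
liposome-like (444/48 and 497/52 nm, ρ = 1.35); cell-like presets use
red-shifted, broader bands (451–462 / 506–520 nm, FWHM 55/58 nm) so that
fixtures exercise the fitter's bound handling. Noise is Gaussian at 2% of
the noiseless peak (SNR 50, matching the smoothness of published cuvette
spectra) with an optional Poisson stage for count realism, an optional
water-Raman Gaussian at 433 nm, and a flat baseline; the final signal is
clipped at zero as a detector would report it. The dose law is hyperbolic
saturating, `S_b(c) = S_b0 + ΔS_max·c/(c + K)` with K = 0.3 µM — a
modelling choice reproducing a fast change below ~0.25–0.5 µM that slows at
higher dose, not a mechanistic claim. Preset control/treated `S_b` pairs:
liposomes 0.225→0.255, 0.41→0.46, 0.52→0.54 (ΔS_max > 0); cell lines
0.82→0.59, 0.74→0.66, 0.73→0.64, 0.65→0.61 (ΔS_max < 0).

**Frames.** Bulk lipids sit on a square lattice of spacing `√(bulk APL)`
(default 0.683 nm², a fluid-phase PC packing), optionally jittered; two
mirrored leaflets; four reference pseudo-atoms 0.45 nm below each head.
With a channel, 20 ring lipids are packed 0.25 nm outside a 0.9-nm-radius
cylinder of pseudo-atoms, and a guard ring of bulk-tagged lipids shares the
ring angles at the radius that makes the region owned by the ring lipids
*exactly* a regular 20-gon of per-lipid area `near_apl` (default
0.417 nm²); the lattice is excluded far enough out not to perturb that
boundary, so the planted group means are partition arithmetic, not a
simulation byproduct. The channel centre is drawn uniformly in the box per
seed — analyses must not depend on grid alignment, and ensemble averages
decorrelate the tessellation's discretisation phase. Planted shell waters
are placed inside the carbonyl shells (one per distinct lipid, radius
0.05–0.24 nm); solvent waters stay ≥ 0.5 nm outside the membrane, beyond
any shell, so the planted count is exact. Per-frame packing fluctuation
(`generate_frames(..., apl_jitter_sigma=σ)`) draws each frame's bulk APL
from `N(APL, σ)`, emulating constant-pressure box breathing.

What the generators do *not* emulate: absolute GP values of real systems
(band positions also shift with dose in reality, while presets only move
areas), instrument drift, vesicle scattering backgrounds, force-field
energetics, lipid tilt/splay, or channel asymmetry between leaflets.
Passing tests therefore demonstrate correctness of the estimators under the
assumed two-band/lattice structure, not instrument- or force-field-level
realism.

## Problem sizes and determinism

Test and example workloads are deliberately desk-scale: 100 spectra per
recovery study, ensembles of ≤ 60 frames of ~320 lipids, 100×100 grids
(20×20 where only partition-exact means are needed). All randomness flows
through seeded `numpy.random.Generator` instances; sub-seeds are derived
arithmetically from the config seed, and fixed seeds reproduce outputs
bit for bit. The CLI writes a manifest (seed, config hash, truth) next to
every synthetic dataset.

## Known limitations

* The fixed-asymmetry default trades a small model-mismatch bias for a
  large variance reduction; spectra whose true band asymmetries differ
  between blue and green bands need `asymmetry="free"` and substantially
  higher SNR.
* GP is computed from the measured spectrum, so blank/response errors
  propagate directly into it; the deconvolution parameters are more robust
  to smooth response mis-calibration (scale invariance) but not to
  wavelength-dependent distortion across a band.
* Grid APL per-lipid values carry O(perimeter × cell side) discretisation
  noise; only group sums/means over whole regions are partition-exact.
* The near-channel criterion is lateral-distance-based and takes no account
  of lipid orientation; in strongly deformed membranes a z-aware criterion
  would be needed.
* Trajectory formats requiring external engines (DCD/XTC) are not read;
  convert snapshots to PDB/GRO first.
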