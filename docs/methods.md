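# Methods

This note records the models, parameter choices and numerical decisions
behind `isojump`, in the spirit of a methods appendix: what is assumed,
which constants matter, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Idealized sheet geometry

The peptide (SVKLWTS‑BG‑KTYLEV‑BG‑TKVLQE‑NH₂; residues 1–7, 10–15 and 18–23
in strands 1–3, Aib–Gly turns at 8–9 and 16–17) is built as a **flat,
untwisted antiparallel sheet**: strands along x with a per-residue rise of
3.47 Å, adjacent strand axes 4.8 Å apart, a 25° Cα pleat (out-of-plane
zigzag; carbonyl C and O stay in the sheet plane), and turns placed on small
arcs outside the strand span. Adjacent strands run antiparallel with the
next strand starting at the x position where the previous one ends, which
puts backbone carbonyls into cross-strand columns; the pairs listed in
`cross_strand_pairs` are those columns (carbonyl carbons exactly one strand
spacing apart).

Within a strand, consecutive carbonyls alternate between the two faces.
The per-strand alternation phase is fixed by requiring nearest cross-strand
Cα neighbors to carry **opposite** carbonyl directions, the hydrogen-bond
ring pattern of an antiparallel sheet. For this layout the rule reproduces
the observed orientations without any residue-specific input: Leu4 points
out to the solvent, Val20 points in toward the central strand, and all
central-strand carbonyls are classified inward.

The real molecule is appreciably twisted and its termini frayed; the flat
builder is a deliberate idealization (solution-structure ensembles can be
supplied as PDB backbones through `read_backbone` instead). Consequences of
the idealization are absorbed by the empirical site-energy calibration
below.

## Exciton model and its calibration

One amide I′ oscillator per backbone C=O (23 for this peptide, the
C-terminal amide included). Transition dipoles have magnitude 0.37 D,
are tilted 20° from the C=O bond toward the C–N bond, and sit 0.65 of the
way from C to O — all common amide I conventions, all configurable.
Couplings are point-dipole (R⁻³) with prefactor 5033 cm⁻¹·Å³/D² and a
dielectric screening divisor of 2.

Two empirical constants depart from pure TDC, both documented here because
they were **fixed by calibration against the observed band pattern** (the
same philosophy as the empirical force-field scaling used in the original
quantum-chemical analysis):

* **Covalent neighbors:** the point-dipole approximation is unreliable at
  one-bond separation. The canonical fixture replaces nearest-neighbor TDC
  with a uniform through-bond constant of **−3.3 cm⁻¹** (the
  `nn_override` hook; `build_hamiltonian` itself defaults to TDC). Raw TDC
  values for neighbors in this geometry (≈ −6 cm⁻¹) push the bright mode
  too high and invert the observed main-band upshift upon labeling;
  strongly positive values (as some coupling maps suggest) concentrate
  intensity at the exciton band bottom and put the main band ~10 cm⁻¹ too
  low. −3.3 cm⁻¹ is the value at which the calibrated model reproduces,
  simultaneously, the three single-label ¹³C maxima (1594/1607/1588 cm⁻¹
  within 1 cm⁻¹), the unlabeled main band at 1634 cm⁻¹, and a main band of
  every labeled variant at or above the unlabeled one.
* **Turn carbonyls** are not cross-strand hydrogen bonded and absorb
  higher; they carry a +25 cm⁻¹ site offset (`delta_turn`). Without it the
  four turn sites pile onto the low edge of the ¹²C band and distort the
  main-band position. `delta_turn` is excluded from calibration and turn
  units are excluded from the solvent-exposure correction.

`calibrate()` adjusts three parameters — ν₀, δ_out (solvent-exposed
carbonyls) and δ_central (central strand) — by least squares so the
predicted ¹³C band maxima of the three single-label variants match their
observed positions. It runs in two stages: first a smooth match of the
labeled-mode eigenvalue, then a polish against parabolic-refined band
maxima of spectra evaluated on a 4× finer internal grid (the refined
maximum of a 1 cm⁻¹ grid is only piecewise smooth, which stalls
derivative-based optimizers ~0.1 cm⁻¹ from the optimum). For the canonical
geometry the calibrated values are ν₀ ≈ 1629, δ_out ≈ +5.7,
δ_central ≈ +20.8 cm⁻¹; the ¹³C isotope downshift is held at 40 cm⁻¹.

Spectra are sums of unit-area Lorentzians (default FWHM 12 cm⁻¹, typical of
amide I′ in D₂O) on a 1550–1720 cm⁻¹ grid at 1 cm⁻¹ spacing. `band_maxima`
returns grid local maxima ordered by descending absorbance with ties broken
toward lower wavenumber; parabolic refinement is available but off by
default so reported maxima correspond to the grid convention. Difference
spectra normalize both inputs to unit band integral over 1570–1700 cm⁻¹
before subtracting, which makes them invariant to sample scaling.

What the model does *not* attempt: absolute quantum-chemical frequencies,
the amide II region, the experimentally unassigned ~1610 cm⁻¹ side band of
Val20-containing variants, and the experimental 4–13 > 13–20 coupling
asymmetry (which the original computations also did not reproduce — in this
model, as in those, the two cross-strand couplings are similar).

## Two-state melting

Van't Hoff with temperature-independent ΔH (ΔCp = 0): the analysis only
extracts an *apparent* T_m, so the simplest defensible model is used. The
thermal fixture uses T_m = 73 °C and **ΔH = 60 kJ/mol**; the experiment
reports no enthalpy, and 60 kJ/mol makes the 5–95 °C transition "very
gradual" (derivative-peak half-width ≈ 30 °C), matching the qualitative
description. The disordered state is a Gaussian of FWHM 40 cm⁻¹ (broader
than the folded main band) whose center drifts linearly 1648 → 1652 cm⁻¹;
the drift is applied as its exact first-order expansion so the noise-free
temperature × wavenumber matrix has rank ≤ 3, a property the tests assert.

`melting_temperature` reproduces the experimental recipe: SVD, sign-fixed
second temperature loading, central-difference derivative, Gaussian peak
fit. One numerical choice matters: the Gaussian is fit only to the
contiguous points above 40% of the derivative's peak height. Fitting the
full curve lets the peak's skew (the 1/T² factor of df/dT, plus truncation
at 95 °C) bias the center by up to ~1.5 °C; the windowed fit recovers
generator truth within ~0.5 °C for ΔH between 40 and 120 kJ/mol at 5 °C
sampling. On the thermal fixture the procedure returns 73.9 °C for a
73 °C generator — the residual +0.9 °C is the procedure's intrinsic bias at
this low cooperativity, and is reported as-is rather than corrected.

## T-jump forward model and inverse chain

Time grids are logarithmic over 300 ns – 1.2 ms (200 points) since the
dynamics span four decades. The solvent response is a step of amplitude
ΔA_solv(T_i → T_f) decaying with a 2 ms thermal-diffusion constant; the
calibration table maps temperature to solvent absorbance at 12.5 mOD/°C, so
the default 100 mOD pump amplitude corresponds to the nominal ~8 °C jump
(smaller jumps are used automatically for final temperatures near 5 °C).
Peptide amplitude is 10 mOD; noise is white Gaussian with σ =
(amplitude/SNR)·√n_averaged per shot, divided by √n_averaged after
averaging (n = 1000), emulating ~1000 averaged transients; SNR 20 is the
registry default.

Solvent subtraction chooses the scale s minimizing the squared residual
slope of (sample − s·solvent) over the final time decade — equivalently the
ratio of OLS slopes — which implements the "flat baseline after peptide
relaxation" criterion; the peptide term is ≈ e⁻³⁴ there and cannot bias s.
The monoexponential fit (lmfit) is initialized from a log-linear regression
of the early decay and flags τ outside [10 ns, 10 ms] as unreliable.
Arrhenius fitting is unweighted linear regression of ln k on 1/T; τ(10 °C)
is the interpolated value and the quoted error is the mean absolute τ
residual of points with final temperature within 10 ± 3 °C (all points,
flagged, if none fall there).

Per-variant Arrhenius parameters are under-determined by the published
numbers (τ at 10 °C per band, plus the ~1 µs at 50 °C trend); the registry
solves exactly that two-point constraint, reproducing every printed anchor
without inventing further numbers. The resulting activation energies
(≈ 5–25 kJ/mol) are modest, as expected for relaxation rates dominated by
the folding direction below T_m.

Kinetic mode weights per probe band default to the identity (each band
relaxes with its own fixture rate); when a structure is supplied,
`mode_weights_from_hamiltonian` maps exciton eigenvectors to site weights
as |c_im|² weighted by mode intensity and a Lorentzian factor at the probe
position — a declared modeling choice, since the experimental mixing claim
is directional, not quantitative. The mixing direction itself (a faster
coupled oscillator raises k_obs, a slower one lowers it, k_obs bounded by
the component rates) is verified numerically by brute-force monoexponential
fits over weight grids.

## What the synthetic tests show — and what they do not

Generated data embody the registered truth exactly: two-state melting, pure
Arrhenius rates, monoexponential bands, white noise, a perfectly flat
sheet. Passing the recovery tests therefore demonstrates that the
*processing chain* is correct and unbiased at the stated noise level
(τ within ±20% at SNR 20; T_m within ±2 °C), not that the underlying
physical model is adequate for any particular real peptide. Real data add
structure the generator deliberately omits: spectral baseline drifts,
stretched/multi-exponential relaxation, temperature-dependent band shapes,
residual TFA and water-vapor lines, and coupling asymmetries of the twisted
structure.

## Problem sizes and determinism

The full test suite and the acceptance script run in seconds on one CPU:
spectra involve 23×23 eigenproblems; melting analysis uses 19 temperatures
× 171 wavenumbers; each kinetic recovery simulates 6 final temperatures ×
200 samples. All stochastic paths take explicit integer seeds
(numpy `default_rng`); regeneration with the same seed is bit-identical,
and the dataset manifests record seeds, truth values (with their table
citations) and file checksums.
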