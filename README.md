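# isojump

Forward modeling and analysis of **¹³C isotope-edited amide I′ IR spectra**
and **temperature-jump relaxation kinetics** for a designed three-stranded
antiparallel β-sheet peptide (SVKLWTS‑BG‑KTYLEV‑BG‑TKVLQE‑NH₂, B = Aib),
with backbone carbonyls labeled at Leu4, Leu13 and/or Val20.

The package is aimed at vibrational spectroscopists and biophysicists who
want a desk-scale, fully synthetic re-implementation of this analysis:
every stage — spectra, melting curves, T-jump transients — can be generated
from registered "truth" parameters and then re-analyzed, so the whole
processing chain is testable end to end without instrument data.

## What it computes

**Exciton model of the amide I′ band.** Each backbone C=O is a local
oscillator with site energy

ν_i = ν₀ + δ_out·[outward] + δ_central·[central strand] + δ_turn·[turn] − δ_iso·[¹³C]

(δ_iso ≈ 40 cm⁻¹ for ¹³C substitution), coupled through transition-dipole
coupling with the familiar R⁻³ form

V_ij = A·[μ̂_i·μ̂_j − 3(μ̂_i·n̂)(μ̂_j·n̂)]·|μ|² / (ε·R³_ij).

Diagonalizing gives delocalized modes; broadened they yield the variant
spectra. The orientation/strand corrections are **calibrated** against the
three observed single-label band maxima (1594, 1607, 1588 cm⁻¹), standing in
for the quantum-chemical force-field scaling used in the original analysis.

**Equilibrium melting.** A van't Hoff two-state model
(f = 1/(1+exp(−ΔH(1−T/T_m)/RT))) mixes the folded exciton spectrum with a
broad disordered band drifting toward 1648–1652 cm⁻¹; the apparent T_m is
extracted the way it is done experimentally — SVD of the temperature ×
wavenumber matrix, central-difference derivative of the second temperature
loading, Gaussian peak fit.

**T-jump kinetics.** Transients at a probe wavenumber are weighted sums of
exponential relaxations (Arrhenius rates per band) on top of a slowly
decaying D₂O response plus shot-averaged noise. The inverse chain mirrors
the experiment: solvent-absorbance temperature calibration, scaled solvent
subtraction to a flat tail, monoexponential fit over 300 ns – 1.2 ms,
Arrhenius fit across final temperatures, and interpolation of τ to 10 °C.
`effective_rate` quantifies the coupled-oscillator mixing rule: adding a
faster-relaxing component to a probed band raises k_obs, a slower one
lowers it, with k_obs always bounded by the component rates.

## Worked example

```bash
isojump report --no-kinetics
```

```
# Band maxima (cm^-1), synthetic calibrated spectra
variant     13C bands         beta-sheet
1W          n.a.                    1634
1W-4        1594                    1634
1W-13       1607                    1635
1W-20       1588                    1634
1W-4-13     1595, 1607              1634
1W-13-20    1588, 1607              1635
1W-4-13-20  1592, 1607              1634
```

The unlabeled variant shows the antiparallel-sheet main band at 1634 cm⁻¹;
single labels produce isotope bands at 1594 (Leu4, solvent-facing), 1607
(Leu13, central strand) and 1588 cm⁻¹ (Val20, pointing into the sheet) —
the position encodes the local environment, not just the mass change —
and every labeled variant's main band sits at or above the unlabeled one,
because removing ¹²C oscillators shortens the coupled segments.

Kinetics, from the library:

```python
from isojump import fixtures as fx
from isojump.tjump import SolventModel, recover_tau

fixture = fx.variant_fixture("1W-13-20")
fit = recover_tau(fx.site_kinetics(fixture), SolventModel(),
                  probe_wn=1588.0, snr=20.0, seed=42)
print(f"tau(10 C) = {fit.tau_at_ref*1e6:.2f} us (+/- {fit.error*1e6:.2f})")
```

```
tau(10 C) = 1.31 us  (+/- 0.05)
```

i.e. the double-labeled variant's 1588 cm⁻¹ band relaxes in ~1.3 µs at
10 °C — faster than the 2.74 µs of the single-label 1W-4, the signature of
coupling to the faster central-strand oscillator.

Melting, from the CLI:

```bash
isojump simulate-melt --variant 1W --out melt.csv
isojump analyze-melt melt.csv          # -> "apparent_tm_C": 73.85
```

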