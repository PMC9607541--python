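# fluorbind

Fluorescence-spectroscopy analysis of small-molecule binding to serum
albumin, plus inhibition statistics for non-enzymatic glycation (AGE)
assays.

## What it is for

When a drug-like molecule binds a fluorescent carrier protein such as
bovine serum albumin (BSA), it quenches the protein's intrinsic
tryptophan/tyrosine emission.  A titration of that quenching carries the
whole binding story, and `fluorbind` extracts it end to end:

- **Quenching mechanism** — Stern–Volmer analysis, F₀/F = 1 + K_sv[Q],
  with K_q = K_sv/τ₀ (τ₀ ≈ 10⁻⁸ s) and a static/dynamic/indeterminate
  call from the temperature trend of K_sv and the diffusion ceiling
  K_q ≷ 2×10¹⁰ L mol⁻¹ s⁻¹.
- **Binding constant and stoichiometry** — the double-logarithmic fit
  log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q].
- **Thermodynamic force decomposition** — van't Hoff analysis
  ln K_a = −ΔH/RT + ΔS/R, ΔG = ΔH − TΔS, with sign-rule classification of
  the dominant interaction (hydrophobic / van der Waals + hydrogen bond /
  electrostatic).
- **Binding-site assignment** — competitive displacement against the
  albumin site markers warfarin (site 1, subdomain IIA), ibuprofen
  (site 2, IIIA) and methyl orange (site 3), via the ratio 100·K′a/K_a.
- **Conformational readout** — synchronous-fluorescence peak-shift
  detection (Δλ = 15 nm → Tyr, Δλ = 60 nm → Trp) and a UV 280 nm trend
  check.
- **Glycation assays** — inhibition rates 100·(1 − F/F₀) for fructosamine,
  fluorescent AGE species, glycoxidation products and the thioflavin-T
  fibril index, with the standard excitation/emission registry.

A seeded synthetic-data module generates titrations, temperature series,
synchronous stacks and assay panels with known ground truth, so every
stage is testable without laboratory data.  See `docs/methods.md` for the
model details and caveats.

## Worked example

```python
from fluorbind import (SyntheticConfig, simulate_temperature_pair,
                       simulate_titration_series, fit_stern_volmer,
                       fit_double_log, fit_vant_hoff)

# a noisy Stern-Volmer titration (1% intensity noise) and its fit
series = simulate_titration_series(
    SyntheticConfig(mode="stern_volmer", noise_cv=0.01, seed=42))
sv = fit_stern_volmer(series)
print(f"Ksv = {sv.Ksv:.3e} L/mol (r2 = {sv.r_squared:.4f}), "
      f"Kq = {sv.Kq:.3e} L/mol/s")

# noiseless binding titrations at two temperatures -> van't Hoff
ka_by_t = {}
for s in simulate_temperature_pair(SyntheticConfig(mode="hill_binding")):
    b = fit_double_log(s)
    ka_by_t[s.temperature] = b.Ka
    print(f"T = {s.temperature:g} K: Ka = {b.Ka:.3e} L/mol, n = {b.n:.2f}")

th = fit_vant_hoff(ka_by_t)
print(f"dH = {th.dH:.2f} kJ/mol, dS = {th.dS:.2f} J/mol/K")
print(f"dG(298) = {th.dG_per_T[298.0]:.2f} kJ/mol, forces: {sorted(th.force_types)}")
```

prints

```
Ksv = 1.247e+05 L/mol (r2 = 0.9984), Kq = 1.247e+13 L/mol/s
T = 298 K: Ka = 3.798e+04 L/mol, n = 1.50
T = 308 K: Ka = 1.933e+04 L/mol, n = 1.50
dH = -51.53 kJ/mol, dS = -85.25 J/mol/K
dG(298) = -26.13 kJ/mol, forces: ['hydrogen bond', 'van der Waals']
```

The fitted K_sv is within 3% of the generator truth (1.21×10⁵ L/mol)
despite the noise; K_q ≈ 10¹³ L mol⁻¹ s⁻¹ sits three orders of magnitude
above the collisional ceiling, the static-quenching signature.  The
binding constants halve from 298 K to 308 K, and the negative ΔH and ΔS
type the interaction as van der Waals plus hydrogen bonding, spontaneous
(ΔG < 0) at both temperatures.

## Command line

A thin CLI wraps the library:

```sh
fluorbind simulate --mode hill_binding --seed 1 --out-dir sim/
fluorbind fit-sv sim/titration_298K.csv --temperature 298
fluorbind fit-binding sim/titration_298K.csv --temperature 298
fluorbind thermo ka_table.csv
fluorbind displace --probe-free free.csv --probe warfarin=war.csv --probe ibuprofen=ibu.csv
fluorbind glycation panel.csv --control control
fluorbind syncshift spectra.csv --delta-lambda 60
fluorbind run workflow.yaml     # full pipeline from a manifest
```

Inputs are delimited text (`conc,intensity` titration tables;
`wavelength_nm,I_<conc><unit>,…` spectra stacks; long-format
`condition,species,replicate,value` assay panels); outputs are diff-able
key-value reports and TSV tables.

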