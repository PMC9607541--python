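# Methods

## Scope and model

`fluorbind` analyses the interaction of a small-molecule quencher with a
fluorescent carrier protein (the motivating system is a fungal metabolite
binding bovine serum albumin, BSA) from steady-state fluorescence
titrations, and computes inhibition statistics for non-enzymatic glycation
assays on the same protein.  The analysis chain is:

1. **Titration readout.** The protein emission band (λ_ex = 280 nm, peak
   near 340 nm for BSA) is read either at a fixed wavelength (default
   340 nm, the primary readout) or as the vertex of a quadratic fitted
   around the local band maximum (sub-gridpoint peak tracking, used by the
   synchronous-shift stage).  Concentrations are held internally in mol/L.

2. **Stern–Volmer analysis.** F0/F = 1 + K_sv[Q] is fitted by unweighted
   ordinary least squares with a free intercept.  The bimolecular quenching
   rate constant is K_q = K_sv/τ0 with τ0 = 1e-8 s, the canonical
   unquenched lifetime of protein fluorophores.  The mechanism call
   combines two standard signatures: static quenching (ground-state
   complex) shows K_sv falling with temperature and K_q far above the
   diffusion-collision ceiling of 2.0e10 L/mol/s; dynamic (collisional)
   quenching shows the opposite pair.  Conflicting signatures yield
   "indeterminate" with both criteria reported.  The ceiling is
   configurable.

3. **Double-logarithmic binding fit.** log10((F0−F)/F) regressed on
   log10[Q] gives the association constant K_a = 10^intercept and the
   binding-site number n = slope ("lg" is log base 10, standard in this
   literature).  Points with F ≥ F0 carry no binding signal and are
   excluded (and counted); the standard error of K_a follows from the
   intercept by the delta method.  Note that both K_sv and K_a are labelled
   L/mol here (so K·[Q] is dimensionless), although parts of the
   literature print them as "mol/L".

4. **van't Hoff thermodynamics.** ln K_a = −ΔH/(R·T) + ΔS/R with
   R = 8.314 J/mol/K.  Two temperatures give an exact solve, three or more
   an OLS fit.  ΔG(T) = ΔH − T·ΔS; the −RT·ln K_a route is computed
   alongside and a discrepancy above 0.5 kJ/mol between the two routes is
   flagged rather than silently averaged.  One fit has one ΔS: tables that
   print a different ΔS per temperature cannot come from a single van't
   Hoff line, and the discrepancy report is the honest way to surface
   that.  The sign rules for force typing are the conventional ones:
   ΔH>0 ∧ ΔS>0 → hydrophobic; ΔH<0 ∧ ΔS<0 → van der Waals + hydrogen
   bonding; ΔH<0 ∧ ΔS>0 → electrostatic; zeros are boundary cases and the
   (+,−) cell is outside the canonical rules.

5. **Site-marker displacement.** Warfarin marks albumin site 1 (subdomain
   IIA), ibuprofen site 2 (IIIA), methyl orange site 3.  The per-point
   statistic is the *ratio convention* 100·F2/F1 (intensity with the probe
   over intensity without); it is a retained-quenching ratio, not the
   complementary 1 − F2/F1, and is labelled accordingly.  The site call
   re-fits K'_a with each probe pre-bound and assigns the site of the probe
   with the minimum 100·K'_a/K_a, provided that ratio is below 60% and the
   runner-up is at least 10 points higher.  Both thresholds are package
   choices — competitive-displacement studies usually argue qualitatively —
   and are configurable; with typical published constants the rule is
   decisive (warfarin ≈ 26%, methyl orange ≈ 45-47%, ibuprofen ≈ 89%).

6. **Glycation statistics.** Inhibition = 100·(1 − reading_with /
   reading_without) for both fluorescence and absorbance readouts, SD by
   error propagation through the ratio.  Some sources print the absorbance
   form inverted, (1 − A0/A); that form is negative for any inhibitor that
   lowers absorbance, so the uniform convention is used and the inversion
   treated as typographical.  The wavelength registry ships the standard
   excitation/emission pairs for total AGEs (350/440), vesperlysine
   (350/405), crossline (380/440), argpyrimidine (320/380), pentosidine
   (335/385), the glycoxidation products dityrosine (330/415), kynurenine
   (365/480) and N'-formylkynurenine (325/434), and thioflavin T
   (440/485).  The ThT fibril index is the plain treated/control intensity
   ratio.  The ANOVA + Tukey HSD layer is a convenience wrapper over
   scipy.stats, not a contribution.

7. **Synchronous-fluorescence shift.** At offset Δλ = 15 nm the
   synchronous spectrum isolates tyrosine, at 60 nm tryptophan.  The band
   maximum per concentration is tracked by quadratic-vertex extraction;
   shift = peak(max conc) − peak(0), called red/blue beyond a ±0.5 nm
   threshold (instrument-resolution scale; the literature calls "slight"
   shifts without a numeric criterion).  The quenching degree is
   1 − I(max)/I(0).  A UV trend helper reports the direction of the 280 nm
   absorbance with titrant (Kendall τ at α = 0.05) as qualitative evidence
   of complex formation; no quantitative UV model is attempted.

## Synthetic data

The generators provide every stage with data of known truth.  Defaults are
the study conditions of the motivating system: F0 = 1000 (arbitrary
units), the 6-point grid 0–10 μM in 2 μM steps, K_sv = 1.21e5 L/mol,
K_a = 3.79e4 L/mol with n = 1.5 at 298 K, ΔH = −51.53 kJ/mol,
ΔS = −85.25 J/mol/K (which reproduce the 298/308 K binding constants
3.79e4/1.93e4 via van't Hoff), and a Gaussian emission band centred at
340 nm with 25 nm width.  Noise is multiplicative Gaussian on intensities
(photon-counting-like relative error), applied to every point and fully
determined by one integer seed; temperature series spawn independent
substreams from that seed.  The default temperature is 298 K.

Two titration modes exist because the Stern–Volmer law and the double-log
law with n ≠ 1 are different generative models: `stern_volmer` gives
F = F0/(1 + K_sv[Q]), `hill_binding` gives F = F0/(1 + K_a[Q]^n).  This
makes the internal tension of fitting both laws to one dataset testable
instead of hidden.  One consequence is worth stating plainly: with
K_a = 3.79e4, n = 1.5 and [Q] in mol/L, the double-log law predicts only
~0.1% quenching at 10 μM — orders of magnitude below the ~55% the
Stern–Volmer constant implies — so noisy-recovery tests of the double-log
fitter use K_a = 1.21/(1e-5)^1.5 ≈ 3.8e7, the value that makes the law
match the observed quench magnitude at the top of the grid.  A second
consequence is statistical: K_a = 10^intercept extrapolates ~5.3 decades
beyond the sampled log10[Q] range, amplifying residual noise by
√(1/N + x̄²/S_xx) ≈ 9.6, so at 1% intensity noise on the 6-point grid the
median relative error of K_a is tens of percent no matter the true
parameters, while K_sv (an interpolated slope) recovers to ~2%.
Single-digit-percent uncertainties printed for intercept-derived binding
constants should be read with that in mind.

What the generators do **not** emulate: inner-filter attenuation (no
correction is applied anywhere, and none is claimed), scatter and baseline
structure beyond a flat band, lifetime or anisotropy photophysics, and the
chemistry of the glycation cascade (assay panels draw readings directly
from a chosen true inhibition fraction).  Passing tests therefore show the
*inference* chain is correct under its stated model, not that the model
captures every artefact of real cuvette data.

## Numerical choices and edge cases

- Unweighted OLS throughout (no weighting scheme is standard for these
  fits); `scipy.stats.linregress` supplies parameter standard errors.
- A constant-intensity titration has an undefined correlation coefficient;
  it is reported as K_sv = 0 with r² = 0 rather than NaN.
- Peak extraction requires ≥5 samples in the fit window, falls back to the
  grid maximum (flagged unreliable) when curvature is non-concave or the
  vertex leaves the window, and warns when the maximum sits on a boundary.
- Zero-concentration rows are mandatory in titration files (they define
  F0) and at least 3 nonzero concentrations are required for any fit.
- Duplicate concentrations are an error naming the offending rows;
  delimiters are auto-detected among comma/tab; decimal points only.
- Report files are plain key-value text and TSV, written with fixed float
  formatting so reruns are byte-identical.

## Limitations

Binding-pose structure (docking/MD), circular-dichroism secondary
structure, modified Stern–Volmer (Lehrer) accessible-fraction analysis,
global multi-temperature fitting, heat-capacity-corrected (curved) van't
Hoff models and microscopy image quantification are out of scope.  The
displacement thresholds and the shift-call threshold are heuristics chosen
for reproducibility, not community standards.
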