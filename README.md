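# specbind

Spectroscopic analysis of small-molecule binding to serum albumin and of its
consequences for protein stability: Stern–Volmer fluorescence quenching,
double-logarithmic binding isotherms, van't Hoff thermodynamics,
residence-time kinetics, circular-dichroism mean residue ellipticity, and
two-step three-state chemical-denaturation free-energy analysis — plus a
synthetic-data generator that provides exactly known ground truth for every
estimator.

It is written for bench scientists and computational chemists who run
fluorescence quench titrations and urea-denaturation experiments on
ligand/protein systems (the bundled defaults describe a drug-like ligand
binding bovine serum albumin) and want the data analysis to be scripted,
validated and reproducible instead of living in a spreadsheet.

## The models

**Quenching and binding.** For a quencher Q, the Stern–Volmer relation

    F0/F = 1 + Ksv [Q],        kq = Ksv / τ0

is fitted by least squares with a free intercept (a baseline diagnostic);
τ0 = 5 ns is the unquenched lifetime of serum albumin. With kq far above the
diffusion-collision ceiling (~10¹⁰ M⁻¹s⁻¹) and Ksv falling as temperature
rises, quenching is classified as *static* (ground-state complex formation).
The association constant Ka and site number n come from the double-log
transform of the same titration:

    log10[(F0 − F)/F] = log10 Ka + n · log10[Q]

**Thermodynamics and kinetics.** ln Ka vs 1/T (van't Hoff) yields
ΔH = −R·slope and ΔS = R·intercept; ΔG(T) = ΔH − TΔS. With a
diffusion-limited forward rate kf = 4π r D N_A ×10³ (Smoluchowski), the
complex residence time is τ = 1/k_b = Ka/kf.

**Stability.** Urea unfolding of albumin is three-state, N ⇌ I ⇌ U. Each
step is analyzed as a two-state equilibrium: linear baselines over the pre-,
intermediate- and post-transition windows convert signal to fractions
f = (y − y_N)/(y_I − y_N); the linear extrapolation model
ΔG(u) = ΔG^H₂O − m·u is fitted either on per-point free energies
ΔG = −RT ln(f/(1−f)) (LEM) or directly in fraction space (nonlinear).
Ligand-induced stabilization is ΔΔG^H₂O = ΣΔG^H₂O(complex) − ΣΔG^H₂O(apo).

**CD.** Raw millidegrees convert to mean residue ellipticity
[θ] = mdeg/(10·n_res·l·C) in deg·cm²·dmol⁻¹; the 268/262 nm ellipticity
ratio is the near-UV tertiary-structure diagnostic.

Everything is exposed both as scikit-learn-style estimators
(`SternVolmerRegression`, `DoubleLogBindingRegression`, `VantHoffRegression`,
`LinearExtrapolationRegression`, `TwoStateDenaturationCurve`,
`ThreeStateUnfoldingAnalysis` — `fit`/`predict`/`get_params`, fitted
attributes with trailing underscores) and as plain functions
(`fit_stern_volmer`, `fit_double_log`, `fit_vant_hoff`, `analyze_profile`,
`compare_stability`, ...).

## Worked example

```python
import numpy as np
from specbind import (QuenchTruth, generate_quench, fit_stern_volmer,
                      fit_double_log, fit_vant_hoff, diffusion_limited_kf,
                      residence_time)

grid = np.linspace(0.0, 18e-6, 19)          # 0-18 uM ligand
series = generate_quench(QuenchTruth(ka_assoc_per_M=6.02e4, n_sites=1.03), grid)

sv = fit_stern_volmer(series)
bind = fit_double_log(series)
thermo = fit_vant_hoff([(293, 6.85e4), (298, 6.02e4), (303, 5.58e4)])
kin = residence_time(bind.ka_assoc_per_M, diffusion_limited_kf())

print(f"Ksv = {sv.ksv_per_M:.3e} M^-1, kq = {sv.kq_per_M_per_s:.3e} M^-1 s^-1")
print(f"Ka = {bind.ka_assoc_per_M:.3e} M^-1, n = {bind.n_sites:.3f}")
print(f"dH = {thermo.dh_J_per_mol/1e3:.2f} kJ/mol, dS = {thermo.ds_J_per_mol_K:.2f} J/mol/K")
print(f"kf = {kin.kf_per_M_per_s:.3e} M^-1 s^-1, tau = {kin.residence_time_s*1e6:.1f} us")
```

prints

```
Ksv = 4.355e+04 M^-1, kq = 8.709e+12 M^-1 s^-1
Ka = 6.020e+04 M^-1, n = 1.030
dH = -15.16 kJ/mol, dS = 40.78 J/mol/K
kf = 3.027e+09 M^-1 s^-1, tau = 19.9 us
```

Reading: the double-log fit recovers the simulated truth (Ka = 6.02×10⁴ M⁻¹,
n = 1.03) exactly on noiseless data. The Stern–Volmer slope on the same
n = 1.03 data differs from Ka because the two relations coincide only at
n = 1; kq ≈ 10¹³ M⁻¹s⁻¹, three decades above the collisional ceiling, is the
static-quenching signature. The van't Hoff fit of the three measured Ka
values gives an exothermic, entropy-favoured binding; with a Smoluchowski
forward rate of ~3×10⁹ M⁻¹s⁻¹ the complex residence time is ~20 µs.

The same workflow runs from the shell (`specbind simulate|fit-sv|classify|
fit-binding|vant-hoff|residence|fit-unfolding|compare|mre`), or as a single
reproducible pipeline with a manifest:

```sh
specbind run --config run.yaml --seed 7
```

## Layout

- `specbind.io_spectra` — CSV/TSV readers/writers, validated containers, background subtraction, JSON result records
- `specbind.synthetic` — ground-truth generators (quench, temperature series, unfolding, scattering)
- `specbind.quenching` — Stern–Volmer fit, mechanism classification, colloid-specificity check
- `specbind.binding` — double-log association constant and site number
- `specbind.thermo` — van't Hoff fit, Smoluchowski rate, residence time
- `specbind.unfolding` — baselines, state fractions, LEM and nonlinear transition fits, ΔΔG
- `specbind.cd` — mean residue ellipticity, near-UV ellipticity ratio
- `specbind.pipeline` / `specbind.cli` — multi-stage reproducible runs

See `docs/methods.md` for the statistical details and design choices.
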