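# Methods

This note documents the models the package fits, the numerical and
statistical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. Units are SI throughout the
code: energies in J/mol, m-values in J/mol/M, concentrations in mol/L;
reports and examples print kJ/mol where the field convention does.
R = 8.3145 J mol⁻¹ K⁻¹ and the default analysis temperature is 298 K.

## Quench titrations

A titration series is ligand concentration vs fluorescence intensity at a
fixed emission wavelength; `intensity[0]` is the ligand-free intensity F0.
Two estimators act on it.

**Stern–Volmer** (`SternVolmerRegression`, `fit_stern_volmer`): OLS of
F0/F on [Q]. The intercept is fitted *freely* rather than pinned at 1: a
pinned intercept hides baseline and dilution errors, a free one exposes
them. A warning is attached when |intercept − 1| > 0.05 (tunable), when any
intensity exceeds F0 by more than 5% (anti-quench), and when the slope is
non-positive or dominated by its standard error. kq = Ksv/τ0 is a derived
field, recomputed on construction so the identity is exact by construction;
τ0 defaults to 5 ns (serum albumin) and is always overridable. Ligand
concentrations are totals as added, not free concentrations — the classical
plots are drawn against added quencher and the package follows that
convention (recorded in result provenance).

**Mechanism classification** (`classify_mechanism`): static if every
kq exceeds the diffusion-collision ceiling (default 10¹⁰ M⁻¹s⁻¹) *and* Ksv
is non-increasing with temperature; dynamic if every kq is at or below the
ceiling and Ksv is non-decreasing; indeterminate otherwise. The temperature
trend uses strict ordering of the point estimates, not a regression slope
test — three temperatures cannot power one. The rule and threshold are
recorded in the report. A fit in isolation is always labelled
indeterminate; the temperature series is what identifies the mechanism.

**Specificity** (`specificity_check`): colloidal ligand aggregates sequester
protein and make apparent Ksv collapse as protein concentration rises. The
check passes when the relative spread of Ksv across protein concentrations,
normalized by the largest value, stays under `max_rel_drop` (default 0.5).

**Double-log binding** (`DoubleLogBindingRegression`, `fit_double_log`):
OLS of log10((F0−F)/F) on log10([Q]); slope = n (site number), intercept =
log10 Ka. Base-10 logarithms, because the plot is read in decades.
The regression is deliberately *unweighted*, matching standard practice for
this plot, although the log-ratio noise is strongly heteroscedastic (the
low-concentration points are noisiest). Points with F ≥ F0 carry no binding
information and are excluded and counted. Consequences users should know:

- the intercept sits far outside the sampled log-concentration range
  (about 5 decades for a micromolar titration), so Ka on the linear scale
  has large, right-skewed error even at 1% intensity noise (~17% sd in
  log10 Ka). log10 Ka and n are the estimates that are unbiased;
  exponentiating inflates the mean by Jensen's inequality.
- a site number outside (0, 4) is flagged as implausible rather than
  rejected.

## Thermodynamics and kinetics

`VantHoffRegression` / `fit_vant_hoff`: OLS of ln Ka on 1/T;
ΔH = −R·slope, ΔS = R·intercept. A two-point input is an exact line, so
standard errors are reported as NaN rather than zero. ΔG at each input
temperature is reported from ΔH − TΔS (the substitution route), and
−RT ln Ka is *also* reported at the same temperatures as a diagnostic: with
a finite temperature series the two routes need not coincide, and reporting
both avoids silently blessing either.

`diffusion_limited_kf`: Smoluchowski rate 4π·r·D·N_A·10³ in M⁻¹s⁻¹ (r in m,
D in m²/s; the 10³ converts m³/mol/s to L/mol/s). The defaults D = 10⁻⁹
m²/s (10⁻⁵ cm²/s) and r = 0.4 nm give 3.03×10⁹ M⁻¹s⁻¹. `residence_time`:
kb = kf/Ka, τ = 1/kb = Ka/kf, stored so the identities are exact. With
Ka ≈ 6×10⁴ M⁻¹ this yields τ ≈ 20 µs. No constant is adjusted to match any
externally quoted rounded value; the formulas are computed as stated.

## Three-state denaturation

The unfolding of serum albumin by urea populates an intermediate:
N ⇌ I ⇌ U. The analysis treats each step as an independent two-state
equilibrium, the classical workflow:

1. **Baselines** (`fit_baselines`): independent OLS lines of signal vs
   denaturant over three user-supplied windows. Defaults (N: 0–2.2 M,
   I: 4.75–5.25 M, U: ≥ 8 M) encode the usual landmarks for albumin —
   unfolding starts near 2.4 M, the intermediate accumulates around
   4.8–5.2 M (the default window is widened to the nearest 0.25 M grid
   points so it holds at least two samples of a standard titration grid).
   Automatic region detection is deliberately not attempted; it is fragile
   on sloped baselines. Each window needs ≥ 2 points; exactly flat data
   short-circuit to a zero-slope line. Each line's OLS parameter covariance
   and the pooled relative residual sd are stored for error propagation.
2. **Fractions** (`state_fractions`): baselines are extrapolated *as lines*
   into the transition zones (sloped native baselines are the norm for
   albumin fluorescence); f_I = (y − y_N)/(y_I − y_N) on the open interval
   between the N and I windows, f_U = (y − y_I)/(y_U − y_I) between I and U
   (the intermediate baseline is the native side of the second step).
   Fractions are clamped to the reporting range [−0.05, 1.05] with
   out-of-range points flagged, not dropped. Near-coincident baselines are a
   hard error. A covariance matrix for the fractions is propagated from the
   measurement noise (diagonal) plus the baseline-parameter covariances
   (shared across points, hence correlated).
3. **Per-point free energies** (`per_point_dg`): ΔG = −RT ln(f/(1−f)) for
   f ∈ [0.05, 0.95] only — the log-ratio diverges at the bounds and points
   outside the band carry no usable free-energy information; the exclusion
   count is reported.
4. **Fits**: `fit_lem` is OLS of ΔG on [urea] (intercept ΔG^H₂O, m = −slope,
   midpoint = ΔG^H₂O/m, exact by construction); `fit_nonlinear` fits
   f(u) = 1/(1 + exp((ΔG^H₂O − m·u)/RT)) directly in fraction space by
   least squares, initialized from the LEM estimate with a coarse restart
   grid as fallback, rejecting non-physical optima (ΔG^H₂O ≤ 0 or m ≤ 0)
   and nearly constant fraction data (non-identifiable). Fitting raw signal
   globally would require re-estimating baselines jointly; that coupling is
   deliberately out of scope.
5. **Stabilization** (`compare_stability`): per side, total ΔG^H₂O is the
   sum over both transitions; ΔΔG^H₂O = total(complex) − total(apo), an
   exact arithmetic identity, with a per-transition breakdown. Mixing fit
   methods across sides is an error.

**Standard errors.** The naive optimizer covariance assumes independent
errors in fraction space and understates the replicate dispersion by about
a factor of two, because all fractions in a zone share the same fitted
baselines. Both fits therefore report sandwich standard errors,
(X'X)⁻¹X'·Cov(f or ΔG)·X(X'X)⁻¹ with X the design matrix (LEM) or model
Jacobian at the optimum (nonlinear) and the covariance propagated from step
2. In 300 seeded replicates at 1% noise the reported error matches the
empirical dispersion (2.60 vs 2.59 kJ/mol sd on ΔG₁^H₂O) and the 3-stderr
interval covers the truth 97.7% of the time.

## The synthetic-data generator

Every estimator has a generator producing data from exactly the model it
fits, so recovery tests isolate estimator correctness from model misfit.

- **Quench** (`generate_quench`): F = F0/(1 + Ka[Q]ⁿ). This reproduces the
  Stern–Volmer line exactly at n = 1 and makes the double-log plot exactly
  linear for every n. The underlying physical binding model of a real
  titration is not specified by these two relations; the saturable form is
  a modeling choice recorded here and in provenance. Defaults: 0–20 µM in
  1 µM steps (20 µL additions of a 2.7 mM stock into 3 mL), F0 = 1000.
- **Temperature series** (`generate_temperature_series`): Ka(T) =
  exp(−ΔH/RT + ΔS/R) exactly, before noise.
- **Noise** is multiplicative lognormal with unit mean and a given
  coefficient of variation (refused at ≥ 0.2 as implausible for this
  instrumentation): fluorescence error scales with intensity, and positive
  intensities keep every log transform defined. The F0 point is left exact
  so that generated series satisfy `intensity[0] = F0` by construction.
- **Unfolding** (`generate_unfolding`), two compositions:
  - `"sequential"` (default): populations from the three-state partition
    function pN = 1/(1+K1+K1K2), pI = K1·pN, pU = K1K2·pN with
    Ki = exp(−(ΔGi − mi·u)/RT), signal = pN·bN(u) + pI·bI(u) + pU·bU(u)
    with linear state baselines. Thermodynamically consistent; pN+pI+pU = 1
    to 1e−12 everywhere.
  - `"two_state_zones"`: encodes the *analysis* assumption instead — inside
    each baseline window the signal lies exactly on the state baseline, and
    in each transition zone it interpolates between the flanking baselines
    with the isolated two-state fraction. This composition is exactly
    invertible by the baseline-fraction pipeline for any parameter values.
  The distinction matters because the two-baseline fraction transform is
  only exact when the transitions do not overlap. At closely spaced
  midpoints (e.g. 4.9 and 6.1 M with m-values of 3.5 and 2.5 kJ/mol/M) a
  sequential profile has all three states populated simultaneously across
  the whole transition region, and the classical analysis of such data is
  intrinsically biased (~15% on ΔG₁^H₂O in that configuration) — a property
  of the method, not of the implementation. Estimator-validation and the
  reproduction script therefore use the zoned composition; the sequential
  composition's pipeline recovery is demonstrated at well-separated truths
  (sharp transitions, plateaus reached within the grid), where it holds to
  <0.1%. Passing recovery tests on zoned data validate the estimators; they
  do not certify the two-state zone assumption for real profiles with
  overlapping transitions.
- **Scattering** (`generate_scattering`): flat level below an aggregation
  threshold, steep linear rise above; threshold `None` means no aggregation.
  Used to exercise the colloid-specificity diagnostics only.

What the generator does **not** emulate: wavelength-resolved emission with
λmax shifts, inner-filter effects, photobleaching, dilution during
titration, instrument drift, or correlated (non-white) noise. Tests passing
on this synthetic data say nothing about those effects in real data.

## I/O and reproducibility

Tables are CSV/TSV with a header row; metadata travel as `# key: value`
comment lines, and explicit arguments (or CLI flags) override them.
Concentrations convert to mol/L on ingest (`conc_unit` ∈ {M, mM, µM}).
Floats are written with 17 significant digits and parsed with pandas'
round-trip parser, so write→read is an identity. No interpolation happens
anywhere in I/O; spectra with mismatched wavelength grids are an error
(silent resampling corrupts ellipticity ratios). Result records serialize
to JSON with the record type, package version and provenance.

The pipeline runner executes simulate → fit → compare stages from one
YAML/JSON config; a seed is mandatory whenever a stochastic stage is
present, every artifact is SHA-256-hashed into a manifest, and identical
config + seed give byte-identical outputs.

The reproduction script (`scripts/acceptance.py`) uses a 0–18 µM, 19-point
titration grid and a 0–9 M, 0.25 M-step urea grid — the dynamic ranges of
the underlying experiments — with noiseless generation, so its outputs are
deterministic parameter recoveries.

## CD conversion

Mean residue ellipticity [θ] = mdeg/(10·n_res·l·C) with n_res = 583 residues
(bovine serum albumin), l in cm, C in mol/L, giving deg·cm²·dmol⁻¹. The
factor-of-10 divisor is the standard convention that makes those units come
out; it is pinned by a unit test so an alternative convention is a one-line
change. The near-UV 268/262 nm ellipticity ratio is read at the nearest
grid points (no interpolation; a grid offset above 0.5 nm is an error) and
is invariant under uniform scaling of the spectrum.

## Known limitations

- Single-wavelength analysis only; no global multi-wavelength fitting.
- No inner-filter correction (a hook accepts pre-corrected intensities);
  no free-ligand iteration (concentrations are totals).
- Linear van't Hoff only (ΔCp = 0); no ITC models.
- No combined static+dynamic (sphere-of-action) quenching model and no
  time-resolved lifetime fitting.
- Three-state analysis assumes the classical independent-two-state
  treatment; no global three-state fit of raw signal with shared baselines.
- CD secondary-structure deconvolution is out of scope; only the MRE
  conversion and shape ratios are provided.
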