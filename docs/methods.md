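# Methods

This note documents the models implemented in `hemobind`, the assumptions
behind them, the defaults and why, and what the synthetic-data generators do
and do not emulate.

## Fluorescence quenching

The observed intensity of a protein titrated with a quenching ligand is
first corrected for the inner filter effect,
F = F_obs·10^((A_ex + A_em)/2), where A_ex and A_em are the sample
absorbances at the excitation and emission wavelengths. The correction is
applied uniformly to every point, including the zero-quencher point that
defines F₀, so ratios are formed from consistently corrected intensities.
The zero-quencher point is part of the titration series itself rather than
a separately supplied scalar — one provenance for F₀ and the fit.

The Stern–Volmer model F₀/F = 1 + K_SV[Q] is fitted by ordinary least
squares of F₀/F on [Q]. Two intercept conventions are offered:

* `free` (default) — slope and intercept both estimated; the correlation
  coefficient r then measures linearity meaningfully.
* `fixed_at_one` — intercept constrained to the theoretical 1; used when
  the unit intercept is taken as part of the model.

The bimolecular quenching rate constant is k_q = K_SV/τ₀. The unquenched
lifetime defaults to **τ₀ = 10⁻⁸ s** (a typical intrinsic protein
fluorescence lifetime of ~10 ns) and is configurable; with this value a
K_SV of n×10⁴ L/mol corresponds numerically to k_q = n×10¹² L mol⁻¹ s⁻¹.

Mechanism classification uses the temperature trend of K_SV across the
supplied fits: strictly decreasing → static (ground-state complex),
strictly increasing → dynamic (collisional), anything else — including a
single temperature or a tie — → indeterminate. With the two or three
temperatures typical of these studies, a trend test with a p-value would
be theater; strict monotonicity is the honest rule. Independently, a
minimum k_q above the diffusion-controlled limit (2×10¹⁰ L mol⁻¹ s⁻¹)
is flagged, since collisional quenching cannot exceed diffusion.

## Binding and thermodynamics

For one set of n equivalent sites, lg((F₀−F)/F) = lg K_a + n lg[Q]; K_a and
n come from an OLS line in log–log space. Points with F ≥ F₀ at nonzero
quencher are rejected as carrying no quenching signal (the transform is
undefined there).

ΔH° is assumed temperature-independent over the narrow experimental range
and estimated by van't Hoff: the closed two-point formula for exactly two
temperatures, otherwise −R times the slope of ln K_a against 1/T (the two
coincide at two points). ΔG°(T) = −RT ln K_a(T), and by default ΔS° is
computed **per temperature** as (ΔH° − ΔG°(T))/T, which preserves the mild
temperature variation such tables usually show; a constant-ΔS° variant
(intercept of the van't Hoff regression) is available via
`constant_entropy=True`. By construction ΔG°(T) = ΔH° − T·ΔS°(T)/1000
holds to machine precision in either mode. R is fixed at
8.314 J mol⁻¹ K⁻¹ with no unit configurability — configurable gas
constants are how silent kJ/J mix-ups happen.

Binding-force classification follows the Ross–Subramanian sign rules:
(ΔH°<0, ΔS°<0) → van der Waals/hydrogen bonds; (>0, >0) → hydrophobic;
(<0, >0) → electrostatic. Values within a zero band — default ±1 kJ/mol
and ±5 J mol⁻¹ K⁻¹, about the resolution of spectroscopic estimates — are
treated as sign-indeterminate and yield `ambiguous`, as does the
(ΔH°>0, ΔS°<0) quadrant, which no single force explains. The mapping is
total and deterministic over the sign plane.

## Circular dichroism

MRE = θ_obs/(10·C_P·n·l) with θ_obs in mdeg, C_P the molar protein
concentration, n the residue count (default 574, the bovine hemoglobin
tetramer) and l the path length in cm. α-helix(%) =
(−MRE₂₀₈ − 4000)/(33000 − 4000)·100: the sign grouping is the one for
which the pure-helix reference MRE₂₀₈ = −33000 gives exactly 100% and the
β/coil crossing −4000 gives exactly 0%. The 208 nm readout is linear
interpolation between the two nearest sampled wavelengths — no smoothing,
which would bias sharp minima. Estimates outside [0, 100]% are returned
with a flag, never clipped: an out-of-range helicity almost always means
wrong concentration units, and clipping would hide that.

## Erythrocyte assays

Hemolysis is affine in sample OD between the two plate controls: the
saline (no-lysis) control maps to 0% and the distilled-water
(complete-lysis) control to 100%. The code names the controls
semantically (`baseline_od`, `full_lysis_od`) rather than
positive/negative, because positive/negative labelling conventions vary
between labs and a swapped label silently negates the scale.

Loading efficiency is (C_original − C_post)/C_original·100 on the
incubation-system concentrations as measured, with no volume-fraction
correction. A post-incubation concentration above the original gives a
negative efficiency with a warning flag instead of an exception —
that outcome is measurement noise, not a logic error.

Calibration is OLS of peak-area ratio on concentration (y = ax + b);
quantitation inverts it and flags extrapolation beyond the standards'
range.

The partition coefficient C_e/p is three-valued: finite when plasma
concentration is positive; infinite when plasma is 0 (below detection)
with drug present in erythrocytes; undefined when both are 0 or either is
missing. 0/0 is deliberately *undefined*, not infinite — no drug detected
anywhere carries no partitioning information. Per-timepoint summaries
report mean and sample SD over the finite ratios only, plus counts of
each kind; a group with only infinite ratios is summarized as infinite.

## Noncompartmental PK

Linear trapezoid throughout for AUC and AUMC (log-linear-down is not
implemented; for richly sampled declining profiles the difference is well
under the other error sources here). λz comes from a log-linear regression
on terminal points; the default selection scans every terminal suffix of
at least three positive concentrations, excluding the observed peak, and
keeps the highest adjusted R², with ties broken toward more points so the
estimate is deterministic. AUC₀–∞ = AUC₀–t + C_last/λz with the
extrapolated fraction reported; MRT = AUMC₀–∞/AUC₀–∞ with the standard
tail terms t_last·C_last/λz + C_last/λz². C₀ for an i.v. bolus is the
log-linear back-extrapolation through the first two positive observations
(falling back, with a flag, to the first observed concentration when the
leading values are nonpositive). CL/F = dose/AUC₀–∞ with dose converted
to μg/kg, so the result is in mL/h/kg. Concentrations below a supplied
LLOQ are dropped before the peak and zeroed after the last quantifiable
value.

## Synthetic data

Generators produce exactly the structure each stage assumes, with ground
truth attached, and are bit-reproducible: each draws from its own
substream, seeded as `SeedSequence([seed, crc32(generator_name)])`, so
adding a generator never perturbs existing fixtures. Noise is
multiplicative lognormal by default (mean-one, specified as a CV), since
intensities and concentrations are positive; additive Gaussian is
available for robustness checks. CD noise is additive in mdeg because
ellipticity changes sign.

Reference defaults mirror the study conditions the package is built
around: a quencher grid of 0–1.75×10⁻⁵ mol/L in 0.25×10⁻⁵ steps,
temperatures (293, 298, 310) K, K_SV ≈ 4×10⁴ L/mol, helicities
36.87%/33.53%, an i.v. C₀ of 2.833 μg/mL with ke chosen to give
t½ ≈ 3.14 h, a hemolysis Hill response with EC50 1.45 mg/mL and Hill
coefficient 18 (reproducing ~0% at ≤1.0, ~58% at 1.5 and ~90% at
1.6 mg/mL), and six-subject partition cohorts at (5, 30, 120) min with
zero-inflated plasma.

What the generators do **not** emulate: baseline drift and scatter in
spectra, plate edge effects, heteroscedastic HPLC error, correlated
within-animal PK deviations, enterohepatic recirculation or any
multi-compartment kinetics, and detection-limit censoring other than
exact zeros. Passing recovery tests therefore demonstrates estimator
correctness under each stage's own model, not robustness to every
artifact of real instruments.

### Problem sizes and stochastic checks

Recovery tests run on the reference grids above (7–11 nonzero points);
dense closed-form PK checks use 0.01 h sampling over 18 h (≈1800 points,
>5 half-lives), where the trapezoid and the analytic one-compartment
forms agree within 1%. Bias checks run 500 seeded replicates at 5% CV
with ≥10 usable points. For K_SV (linear fit) and λz (log-linear slope;
lognormal noise enters additively in log, so the slope is unbiased) the
reference designs are used directly. For K_a the replicate design is a
12-point log-spaced grid spanning K_a[Q] ∈ [1, 50]: the double-log fit
estimates lg K_a as an intercept, so it needs leverage in lg[Q] — on a
narrow arithmetic grid centred 5 decades from [Q] = 1 the intercept
extrapolation makes any estimator's mean error explode (Jensen's
inequality on the back-transform alone exceeds 10%), which is a property
of that design, not of the estimator.

## Known limitations

* The Stern–Volmer and double-log models are the linear forms only; an
  upward-curving combined static+dynamic model is out of scope.
* CD analysis estimates the α-helix fraction from 208 nm only; no full
  secondary-structure deconvolution.
* NCA handles one profile at a time; no pooled/sparse-sampling designs
  and no compartmental fitting.
* Published partition tables round concentrations to 3 decimals; ratios
  recomputed from them can differ from a source's printed ratios by up to
  ~0.004 when the source divided unrounded values.
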