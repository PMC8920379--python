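# hemobind

Quantitative analysis of drug–erythrocyte–hemoglobin interactions.

Small cationic drugs such as berberine circulate at puzzlingly low plasma
concentrations while accumulating in tissues. One explanation is that the
erythrocyte — and the hemoglobin inside it — acts as a hidden drug carrier.
Characterising that carrier takes four kinds of quantitative work, and
`hemobind` implements all of them as one tested pipeline for spectroscopists
and DMPK scientists:

1. **Fluorescence quenching & binding** — inner-filter correction
   (F = F_obs·10^((A_ex+A_em)/2)), Stern–Volmer fits
   (F₀/F = 1 + K_SV[Q] = 1 + k_q τ₀[Q]) with static/dynamic mechanism
   classification from the K_SV(T) trend, the double-logarithm one-set-of-sites
   model (lg((F₀−F)/F) = lg K_a + n lg[Q]), and van't Hoff thermodynamics
   (ln(K₂/K₁) = (1/T₁ − 1/T₂)·ΔH°/R, ΔG° = ΔH° − TΔS° = −RT ln K_a) with
   Ross–Subramanian classification of the dominant binding force from the
   signs of (ΔH°, ΔS°).
2. **Circular dichroism** — mean residue ellipticity
   MRE = θ_obs/(10·C_P·n·l) and α-helix content
   (−MRE₂₀₈ − 4000)/(33000 − 4000)·100, plus the helicity change on ligand
   binding.
3. **Erythrocyte carrier assays** — hemolysis rate from plate absorbances,
   drug-loading efficiency, internal-standard HPLC calibration
   (y = ax + b) and quantitation, and the three-valued erythrocyte/plasma
   partition coefficient C_e/p (finite / ∞ when plasma is below detection /
   undefined at 0/0).
4. **Noncompartmental pharmacokinetics** — linear-trapezoid AUC₀–t, terminal
   λz by best-adjusted-R² log-linear regression, t½ = ln2/λz, AUC₀–∞, MRT,
   CL/F, and C₀ (i.v.) or C_max/T_max (oral).

A seeded synthetic-data module generates inputs with exactly the structure
each stage assumes (Stern–Volmer titrations with inner filtering, binding
isotherms, van't Hoff K_a(T) series, two-band CD spectra, Hill-response
hemolysis plates, one-compartment i.v./oral profiles, zero-inflated
partition cohorts), so every estimator is verifiable by parameter recovery.

## Worked example

Fit Stern–Volmer models at three temperatures on synthetic titrations whose
K_SV(T) follows a van't Hoff law with ΔH° = −4.7495 kJ/mol and
ΔS° = 72.113 J mol⁻¹ K⁻¹, then classify the mechanism and the binding force:

```python
from hemobind import SternVolmerModel, VantHoffModel, classify_mechanism
from hemobind import simulate as sim

fits = []
for temp, ka in sim.gen_temperature_series(dH=-4.7495, dS=72.113):
    series = sim.gen_quenching_titration(ksv=ka, temperature=temp)
    fits.append(SternVolmerModel(series).fit())

print(fits[0].summary())
print("mechanism:", classify_mechanism(fits).mechanism.value)
print(VantHoffModel([(f.temperature, f.ksv) for f in fits]).fit().summary())
```

prints

```
Stern-Volmer quenching fit
==========================
temperature        293 K
n (nonzero [Q])    7
intercept mode     free
Ksv                41084.8 L/mol  (se 0)
intercept          1
tau0               1e-08 s
kq = Ksv/tau0      4.10848e+12 L mol^-1 s^-1
r                  1.000000
mechanism: static
Binding thermodynamics
======================
dH  -4.7495 kJ/mol   force: electrostatic
T (K)    dS (J/mol/K)   dG (kJ/mol)
293      72.113         -25.8786
298      72.113         -26.2392
310      72.113         -27.1045
```

Reading: K_SV ≈ 4.1×10⁴ L/mol at 293 K means the quencher halves the
fluorescence near [Q] ≈ 24 μM; k_q = K_SV/τ₀ ≈ 4×10¹² L mol⁻¹ s⁻¹ is far
above the ~2×10¹⁰ diffusion limit, and K_SV falls with temperature — both
hallmarks of static (complex-forming) quenching. The negative ΔH° with
large positive ΔS° classifies the dominant force as electrostatic, and
ΔG° ≈ −26 kJ/mol means binding is spontaneous.

## Command line

Each stage is also a subcommand over the fixed CSV schemas
(`hemobind quench|bind|thermo|cd|hemolysis|loading|partition|nca|simulate`),
and `hemobind run --config study.yaml` executes a whole study, writing one
tidy CSV per stage plus a provenance-stamped summary.

```bash
hemobind simulate quenching --seed 5 --out fixtures/
hemobind quench fixtures/titration.csv
```

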