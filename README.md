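# convdry

Tools for analyzing convective drying of fruit pomace (and similar
fiber-rich plant by-products) and the quality of the resulting powder:

* **thin-layer drying kinetics** — moisture ratio and drying-rate curves,
  equilibrium-endpoint detection, nonlinear least-squares fitting of the
  Page, Modified Page, Henderson–Pabis, Logarithmic and Midilli models, and
  AICc-based model ranking;
* **moisture diffusivity** — effective moisture diffusivity by the Fick
  slab slope method with a geometric correction factor, and Arrhenius
  activation energy across drying temperatures;
* **bioactivity** — percent inhibition and four-parameter-logistic IC50
  estimation for DPPH/ABTS radical-scavenging assays;
* **treatment comparison** — one-way ANOVA and Tukey HSD with a compact
  letter display for replicated quality-property tables;
* **synthetic data** — seeded generators for every input above, so the
  whole pipeline is testable without laboratory data.

It is aimed at food-process engineers and researchers characterizing
drying protocols for functional ingredients.

## The models

A drying run records dry-basis moisture `M_t` (kg H₂O per kg dry solid) at
fixed intervals. The dimensionless moisture ratio

    MR(t) = (M_t − M_e) / (M_0 − M_e)

decays from 1 toward 0, where `M_0` is the initial and `M_e` the
equilibrium moisture content (declared when the relative weight change
stays below 0.01 % over three consecutive weighings). Five semi-empirical
curves describe MR(t) (t in hours, k in h⁻ⁿ):

| model            | MR(t)                  |
|------------------|------------------------|
| Page             | exp(−k·tⁿ)             |
| Modified Page    | [exp(−k·t)]ⁿ           |
| Henderson–Pabis  | a·exp(−k·t)            |
| Logarithmic      | a·exp(−k·t) + c        |
| Midilli          | a·exp(−k·tⁿ) + b·t     |

Constants are estimated by seeded multi-start bounded least squares
(minimizing SSE), and each fit carries R², χ², MSE, SSE, RMSE, AIC and
AICc; candidate models are ranked by AICc.

Effective moisture diffusivity uses the first term of the Fick slab
solution, `MR = (8/π²)·exp(−π²·D·t/(4L²))`: `D_cal` comes from the slope
of ln(MR) vs t (seconds), `D_eff = D_cal/R_g` with geometric factor
`R_g = 13.1` for a flat tray, and the activation energy follows from
`ln(D_eff)` vs `1/(T+273.15)` via `D_eff = D₀·exp(−E_a/RT)`.

IC50 is the midpoint of `inh(c) = lower + (upper−lower)/(1+(IC50/c)^hill)`
with asymptotes fixed at 0/100 by default.

## Worked example

Simulate one noisy 70 °C drying run, fit all five models, and estimate
diffusivity:

```python
import numpy as np
from convdry import *
from convdry.simulate import SimulationConfig, simulate_drying_experiment
from convdry.fitting import FitOptions

cfg = SimulationConfig(params={"k": 0.6635, "n": 1.0826}, temperature_C=70.0,
                       noise_sd_mr=0.005, seed=11, time_end_min=390.0)
series, truth = simulate_drying_experiment(cfg)
eq = detect_equilibrium(series)                  # 0.01% over 3 weighings
mr = compute_moisture_ratio(series, eq.m_e)
fits = [fit_model(mr, name, FitOptions(seed=0)) for name in MODELS]
for f in rank_models(fits):
    print(f"{f.model_name:16s} k={f.params['k']:.4f} "
          f"R2={f.stats.r_squared:.4f} RMSE={f.stats.rmse:.4f} "
          f"AICc={f.stats.aicc:.2f}")

est = correct_geometry(estimate_dcal(mr, 0.005), 13.1)
print(f"D_eff = {est.d_eff:.3e} m2/s")
```

prints

```
page             k=0.6633 R2=0.9998 RMSE=0.0043 AICc=-147.46
midilli          k=0.6630 R2=0.9998 RMSE=0.0038 AICc=-143.58
logarithmic      k=0.6813 R2=0.9989 RMSE=0.0099 AICc=-120.71
henderson_pabis  k=0.7250 R2=0.9977 RMSE=0.0144 AICc=-113.66
modified_page    k=0.8008 R2=0.9972 RMSE=0.0160 AICc=-110.73
D_eff = 1.949e-10 m2/s
```

The generating Page constant (k = 0.6635 h⁻ⁿ) is recovered to three
decimals and the Page model ranks first by AICc (Midilli matches the data
as well — it nests Page — but pays the AICc penalty for its two extra
parameters). The slope-method `D_eff` reflects the single-term Fick
approximation of a Page-generated curve, not a round trip.

The same analyses are available from the shell:

```sh
convdry simulate --outdir runs --temperatures 50,60,70,80,90 --seed 1
convdry fit --input 70=runs/drying_70C.csv --output fits.csv --seed 1
convdry diffusivity --input 50=runs/drying_50C.csv --input 90=runs/drying_90C.csv \
    --output deff.csv
convdry ic50 --input dose_response.csv
convdry compare --input properties_long.csv --output letters.csv
```

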