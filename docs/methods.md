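# Methods

This note records the modeling choices behind `convdry`, their defaults,
and what the synthetic-data generators do and do not emulate.

## Drying kinetics

Moisture is handled on a dry basis (kg H₂O per kg bone-dry solid).
The equilibrium endpoint is the first weighing at which the relative
change between consecutive values stays below a threshold (default
1e-4, i.e. 0.01 %) across three consecutive measurements — two
consecutive sub-threshold intervals. The criterion is relative, so it
applies equally to moisture or raw mass series (mass input is supported
through the reader given a bone-dry mass). If the criterion is never met
the last point is used and the result is flagged not-converged.

The drying rate over an interval is reported as a positive magnitude,
`DR = (M_t1 − M_t2)/(t2 − t1)`, attached to the interval midpoint;
rewetting intervals keep their negative sign and set a flag. The raw
definition with `t1 − t2` in the denominator would make drying rates
negative, which is not how practitioners report them.

### Time units

Weighing times are minutes. Thin-layer rate constants are expressed **per
hour**: published constants for pomace drying at 50–90 °C (k ≈ 0.26–0.99)
combined with drying times of 210–810 min and equilibrium moisture ratios
of 3.5e-3–1.54e-2 are only mutually consistent on an hour basis — a
per-minute k of that size would flatten the curve within one 30-min
interval. The fitting and simulation layers convert minutes → hours at the
boundary; diffusivity regressions convert minutes → seconds so D is
m²·s⁻¹.

## Model fitting

Fits minimize SSE with `scipy.optimize.least_squares` (trust-region
reflective, bounded) from a heuristic start (k from the log-linear slope
of ln MR vs t; a=1, n=1, b=0, c=0) plus a 5-point Latin-hypercube
multi-start over the bounds, seeded — fits are deterministic per seed and
insensitive to initialization. Bounds: k ∈ (1e-6, 50), n ∈ (0.1, 5),
a ∈ (0.5, 1.5), b ∈ (−0.01, 0.01), c ∈ (−0.5, 0.5); reported constants
fall well inside.

The statistic battery follows the conventional definitions (R², χ², MSE,
SSE, RMSE, AIC = N·ln(SSE/N)+2K, AICc = AIC + 2K(K+1)/(N−K−1)) with three
numerical guards:

* χ² divides each squared residual by the predicted MR with no
  degrees-of-freedom divisor; predictions below 1e-6 are excluded from the
  sum and counted, since the equilibrium tail would otherwise blow the
  statistic up.
* Perfect fits (SSE = 0, routine on noiseless synthetic data) report
  AIC/AICc as −∞ with a `perfect_fit` flag instead of erroring, so they
  rank first naturally.
* When N ≤ K+1 the small-sample correction is undefined; AICc is NaN with
  `aicc_defined=False` rather than an exception.

Ranking is ascending AICc (the small-sample-corrected criterion is the
right one at 8–28 observations per run), ties broken by RMSE then by
fewer parameters, and refuses to compare fits with different N.

## Diffusivity and activation energy

`L` defaults to half the bed thickness (0.005 m for the 0.01 m tray),
configurable for single-sided drying. The ln(MR) regression keeps the
t = 0 point (it lies on the line under the single-term solution) and
drops points with MR ≤ 1e-4 to stay off the equilibrium plateau. The
geometric factor R_g = 13.1 for flat trays is treated as a configurable
constant, not derived. The gas constant is 8.314 J·mol⁻¹·K⁻¹ and E_a is
reported in kJ·mol⁻¹. A temperature-independent diffusivity set returns
E_a = 0 with D₀ equal to the common value.

Note the single-term Fick form is exact only for data it generated; on
thin-layer-model curves the slope method yields an effective, not a
round-trip, diffusivity.

## IC50

Percent inhibition defaults to the standard scavenging convention
100·(A_c − A_s)/A_c; the complementary form 100·A_s/A_c is available as
`convention="as_printed"` for sources that state it that way (the two sum
to 100). The dose–response form is a four-parameter logistic with
asymptotes fixed at 0/100 by default — the natural choice for a percent
scale when the regression form is otherwise unspecified. The fit works on
log-concentration (serial dilutions are geometric), making it exactly
equivariant under concentration rescaling. Responses that never cross
50 % yield an `extrapolated` flag rather than a failure; responses that
decrease by more than 10 percentage points between consecutive
concentrations are rejected as non-monotone beyond noise.

## Treatment comparison

One-way ANOVA is computed from the textbook sums-of-squares decomposition
(cross-checked against `scipy.stats.f_oneway` in the tests); all-zero
within-group variance is a degenerate-input error. Tukey HSD uses the
studentized-range critical value `q(1−α; k, df_w)` with the Tukey–Kramer
standard error for unbalanced groups, and the compact letter display uses
the insert-and-absorb algorithm with letters ordered so the highest mean
gets "a". Letters are assigned per property across all treatments
jointly. Shapiro–Wilk and Levene screens are attached as advisory
p-values only; they never gate the analysis.

Replicate-level data for published property tables are rarely released,
so `simulate_property_table` regenerates pseudo-replicates from printed
mean ± SD (normal, n = 3, seeded). This is approximate: real replicates
need not be normal, and printed SDs are rounded. Cross-temperature
summaries (e.g. a property pooled over 50–80 °C) average group means with
equal weight before the percent-change comparison.

## Synthetic data

The drying generator emulates the study protocol: 30-min weighings to
810 min, 0.01 m bed, five temperatures. MR comes from a thin-layer model
or the Fick slab form, clipped below at an equilibrium floor that rises
linearly from 3.5e-3 at 50 °C to 1.54e-2 at 90 °C (surface hardening
retains more moisture at higher temperature). Moisture conversion uses
M₀ = 4.0 kg·kg⁻¹ db and M_e = 0.05 by default — typical wet-pomace
values, configurable since initial moisture is rarely printed. Noise is
additive Gaussian on MR (default sd 0.005), optionally followed by
quantizing the implied mass at the 0.001 g balance resolution; this is
the simplest model consistent with the stated instrumentation, and the
true error structure (heteroscedastic, drift) is unknowable from
summaries. Noise that drives MR below −0.1 is a configuration error;
smaller negative excursions clip to 0.

Every generator emits a ground-truth record (sidecar text file from the
CLI) so recovery tests never re-enter truth by hand, and all randomness
flows through `numpy.random.default_rng(seed)`.

What passing tests show: the estimation stages recover known parameters
under the stated noise and grids, and derived summary numbers follow from
printed table values. What they do not show: behavior on real drying
curves with case-hardening transients, shrinkage, or non-Gaussian balance
error — the generators deliberately contain no heat/mass-transfer
physics.

## Problem sizes

The test suite's Monte-Carlo studies use 100–200 seeded replicates
(noisy Page fits, model-recovery ranking, IC50 and Tukey-letter
regeneration), 8–28 points per drying curve, and 5-temperature Arrhenius
sets — sizes chosen to make distributional claims stable across reruns
while keeping the suite fast. The acceptance script runs each recovery
once on noiseless inputs, where results are deterministic.

## Known limitations

* No weighted or Bayesian fitting, no parameter confidence intervals
  (a bootstrap hook is a natural extension).
* Single-term Fick solution only; no shrinkage correction or
  temperature-dependent L.
* No psychrometric modeling of the drying air.
* 4PL is the only dose–response form.
* No multiple-testing control across properties in the comparison module.
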