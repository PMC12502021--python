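# Methods

## The model

Photosynthetic heat tolerance (PHT) is quantified from the temperature
response of the dark-acclimated maximum quantum yield of photosystem II,
Fv/Fm. Leaves heated briefly to a target temperature T show a
negative-exponential collapse of Fv/Fm, modelled as

    y(T) = θa · (1 − exp(−(θb + θc·T)))

with θa the unstressed asymptote (dimensionless Fv/Fm), θb a location
constant and θc < 0 the decay parameter (per °C). At low temperatures the
exponential term vanishes and y ≈ θa; as T approaches −θb/θc the curve
collapses through zero. Three thresholds summarise a fitted curve:

* **Tcrit** — the temperature at which the slope of the curve reaches 15%
  of its steepest value. For this model the slope magnitude
  |θa·θc|·exp(−(θb + θc·T)) grows monotonically in T, so "steepest" is only
  defined over a finite domain; we use the group's measured temperature
  range (controls included, ≈ 20–50 °C), which is the only range the data
  could have informed. The closed form is `T_high + ln(0.15)/|θc|`. The
  domain choice is stored with every result, and a fixed-window variant can
  be obtained by overriding the curve's domain before threshold extraction.
* **T50 / T95** — temperatures causing a 50% / 95% reduction of Fv/Fm
  relative to the unstressed value; closed form
  `T = −(θb + ln(1 − c/θa))/θc` with `c = (1 − fraction) · reference`.

The *reference* (unstressed value) is the per-group mean of the leaves'
pre-treatment ambient controls; when a table carries no controls the
published control figure 0.803 is the documented fallback
(`reference_policy="fixed"`).

## Fitting

Parameters are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, xtol = ftol =
1e-8, ≤ 500 evaluations per start). Initialisation is multi-start: θa
starts at the mean control Fv/Fm, θc on a fixed nine-point grid from −0.05
to −2 per °C, and θb is back-solved so each start's curve passes half its
asymptote at the empirical half-decline temperature. The converged start
with the lowest residual sum of squares wins; groups where no start
converges, with fewer than 5 observations, fewer than 3 distinct
temperatures, no decline, or no near-control observation are returned
flagged (`converged=False`), never silently defaulted.

Residuals are computed against the zero-clamped curve `max(y(T), 0)`.
Fv/Fm is physically non-negative, and leaves heated past full collapse
record (near-)zero values while the raw model continues negative; fitting
the raw model against such data biases all parameters (in pilot runs T50 by
≈ −0.5 °C and Tcrit by several °C). With the clamped model, noise-free data
are recovered to machine precision and T50 bias at the default noise level
is ≈ 0.05 °C. Thresholds are always extracted from the raw-model closed
forms.

## Bootstrap

Uncertainty comes from resampling leaf-level rows with replacement (same n,
unstratified by default; stratification within target-temperature levels is
available) and refitting per replicate, warm-started from the full-data
solution with multi-start as fallback. Replicates that fail to converge or
yield an undefined threshold are dropped and counted, never redrawn —
redrawing would bias toward easy resamples. Estimates with under 50%
successful replicates are flagged unreliable. Each species×site×protocol
group receives its own random stream spawned from the global seed in sorted
key order, and group rows are sorted before resampling, so results are
bit-identical across runs and independent of input row order. The reported
central value is the bootstrapped mean; the full-data point estimate is
retained alongside.

## Thermal safety margins

A species' maximum operating leaf temperature, Tleafmax, is the mean of the
upper quartile of its measured midday leaf temperatures at a site
(campaigns pooled by default). The quartile uses the linear-interpolation
75th percentile with inclusive membership (values ≥ Q3): for {1..8} the
quartile is 6.25 and Tleafmax = mean{7, 8} = 7.5. This convention is stable
for small samples; alternatives shift Tleafmax by a few tenths of a °C, so
it is stated prominently here. The thermal safety margin is
TSM = threshold − Tleafmax (T50 by default, Tcrit/T95 selectable); negative
margins mark exceedance, and the exceedance count per site is exactly the
count of species with TSM < 0 (ties do not count). The air-based variant
measures against a per-site maximum air temperature supplied in the trait
table — the package treats that statistic as an input, since its definition
(absolute versus mean daily maximum) varies between datasets.

## Lipid composition and species-mean statistics

The double-bond index (DBI) of a thylakoid lipid class is the
abundance-weighted mean number of acyl double bonds per lipid molecular
species: `Σ abundanceᵢ·bondsᵢ / Σ abundanceᵢ` within species × site ×
class. Mol-based abundances are assumed; a per-acyl-chain reading would
divide by two and affects nothing but a constant factor in slopes. DBI is
invariant under uniform rescaling of abundances, and zero total abundance
is flagged undefined.

Regressions on species-site means use ordinary least squares (statsmodels),
overall and per site; acclimation slopes regress a threshold on growth
temperature or Tleafmax, in °C per °C (1 = full acclimation). Site
comparisons use one-way ANOVA (`scipy.stats.f_oneway`) on species means
followed by Tukey HSD (`statsmodels pairwise_tukeyhsd`), summarised with a
compact letter display computed from maximal cliques of the
non-significance graph (exact for the small numbers of levels used here;
capped at 15 levels). All p-values are two-sided with significance at
p ≤ 0.05 and no correction beyond Tukey. Mixed-effects variants (species as
a random factor) are deliberately out of scope; the package reports the
pooled OLS versions only.

## Synthetic campaign

The generator emulates a three-site (high/mid/low elevation: HE/ME/LE),
twelve-species common-garden campaign: 6 leaves × 7 target temperatures
(34–50 °C) per group with measured temperatures jittered uniformly within
±1 °C of target, additive Gaussian Fv/Fm noise (default SD 0.03, a free
parameter — no empirical residual magnitude was available) truncated at 0,
and per-leaf ambient controls drawn from Normal(0.803, 0.04) truncated to
(0, 0.87].

Default generating curves are back-solved per group from a target Tcrit and
T50 (`thetas_from_thresholds`): the site means 35.6/38.1/38.9 °C (Tcrit)
and 42.8/44.3/45.3 °C (T50) plus fixed zero-centred species offsets
(±2.2 °C for T50, 1.8× that for Tcrit), with the curve anchored through the
control value at the ambient temperature. Two consequences worth knowing:

* With θc fixed by Tcrit and (θa, θb) by the two anchors, T95 is implied,
  landing ≈ 1.3 °C below the campaign's published site means — the model
  cannot hit all three thresholds independently.
* The true Tcrit is defined on the nominal domain edge (50 °C) while a
  fitted group's edge is its realized maximum measured temperature
  (≈ 50.7 °C on average under jitter), so recovered Tcrit sits ≈ +0.7–1 °C
  above truth by construction. T50/T95 are unaffected.

Leaf temperatures are skew-normal (scale 3 °C, skew 4 — midday sun-leaf
temperatures are right-skewed), with locations calibrated so the
population upper-quartile means give species-mean leaf-based TSMs of about
9.3/4.6/1.4 °C per site; species offsets are amplified at the warmest site
so a few species exceed their T50 there. Per-site growth temperatures are
17.5/22.5/23.8 °C and maximum air temperatures 28.3/31.7/35.2 °C. Lipid
class DBI is linear in true T50 (declining for MGDG/DGDG/SQDG, flat for
PG), realised exactly by mixing each class's low- and high-unsaturation
anchor molecular species; traits are linear in the true-T50 anomaly with
clipping to realistic ranges (leaf area 5–228 cm², gs 0.08–0.40 mol m⁻²
s⁻¹, LMA 65–147 g m⁻²).

One global seed drives everything through a fixed stream-splitting rule
(`SeedSequence(seed).spawn(4)` → fluorescence, leaf temperatures, lipidome,
traits), so a seed plus config reproduces every table bit-identically and
generating one table never perturbs another.

What the generator does **not** emulate: within-leaf measurement error
structure beyond additive Gaussian noise, tree-level clustering, seasonal
campaign differences, leaf energy balance (leaf temperatures are drawn, not
modelled), and any nonlinearity in trait–tolerance couplings. Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling design, not robustness to every feature of field data.

## Problem sizes

The test suite and the acceptance script size their simulations as the
package's own calibration choices: the closed-form/root-finder comparison
sweeps 1000 random admissible parameter sets; recovery calibration uses 100
groups of 42 leaves with 200 bootstrap replicates each; the full synthetic
campaign runs 36 groups with 1000 replicates each. Pilot runs froze the
recovery tolerances (T50 |mean bias| < 0.5 °C; bootstrapped means within
1 °C of truth in ≥ 95% of groups) before they were asserted.

## Known limitations

* Tcrit depends on the slope-domain convention; values are comparable only
  under the same convention, which is why the domain is stored with results.
* The bootstrap treats leaves as exchangeable within a group; any real
  tree-level dependence would make the reported SEs slightly optimistic.
* Curves that never reach the 95% reduction within the admissible range
  yield an undefined T95 for that replicate; such replicates are excluded
  and counted rather than extrapolated.
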