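# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic data can and cannot show.

## The CO₂ method

The measured quantity is the CH₄:CO₂ concentration ratio of
background-corrected breath samples; the modelled quantity is the cow's
daily CO₂ excretion, predicted from heat production. Multiplying the two
gives daily CH₄ without a respiration chamber. The chain is deliberately
kept as three isolated operations:

| operation | formula | units |
|---|---|---|
| heat production | HP = 5.6·BW^0.75 + 22·Y + 1.6e−5·P³ | W |
| daily CO₂ | CO₂ = HP/1000 · 180 · 24 | L/day |
| daily CH₄ | CH₄ = ratio · CO₂ | L/day |

The heat-production, CO₂-per-HPU, intake and energy-corrected-milk
formulas are the standard CIGR / Pedersen / Kristensen–Ingvartsen /
Sjaunja forms; every coefficient sits in `FormulaCoefficients` so an
alternative variant (e.g. another CIGR edition) can be swapped in from a
YAML file without touching code. HP is computed once per cow-period from
the period body weight and milk record, not per day, because BW is
recorded once per cow-year.

EDMI places the parity correction d additively on the total
(EDMI = a − 0.5(c−b) + d + c, a/b herd TMR and concentrate means, c
individual concentrate); additive placement on the TMR component is
algebraically equivalent.

## Step I processing choices

- Visit intervals are half-open [entry, exit): a sample at the entry
  time belongs to the visit, a sample at the exit time does not. This
  prevents double assignment at back-to-back visits.
- "Below 400 ppm" is strict: corrected CO₂ exactly 400 ppm is kept.
- A single background pair (grand mean over all disconnection-window
  samples) corrects the entire period; per-day correction is available
  as `background_mode="day"` for sensitivity analysis.
- Negative corrected concentrations are retained; only the CO₂ filter
  removes samples. Negative sample ratios can therefore occur in
  principle (very low CH₄ with high CO₂) and are averaged like any other.
- Ratio aggregation is mean-of-ratios up the sample → visit → day →
  period hierarchy; ratio-of-means (summed CH₄ over summed CO₂) is a
  config switch. The filter is applied before matching conceptually but
  the two commute, since both are row-wise.

## Mixed models

All models are random-intercept linear mixed models fitted by REML
(statsmodels MixedLM). The yearly model uses daily phenotypes with
intake (EDMI), energy-corrected milk (ECM) and parity as candidate fixed
effects, pruned by backward elimination on Wald p-values at α = 0.05
with the AIC trail logged (elimination fits use ML so nested models are
comparable; the final model is refitted by REML). The estimated mean μ̂
entering the CVs is the fixed-effect prediction averaged over the
observed covariate distribution, which reduces to the grand mean for an
intercept-only model.

Numerical details worth knowing:

- Gradient optimisers occasionally stall short of the REML optimum or
  fail on near-singular Hessians when a variance component approaches
  zero. `fit_random_intercept` therefore keeps the best of a gradient
  and a derivative-free (Powell/Nelder–Mead) fit by restricted
  likelihood, and falls back to the zero-cow-variance OLS boundary fit
  (flagged `converged=False`) only if all optimisers fail.
- Exactly degenerate data (within-group sum of squares identically zero)
  sits on an unbounded likelihood ridge; the analytic REML limit is
  returned there (σ²_ε = 0, σ²_cow the ddof-1 variance of group means).
  On balanced noisy designs the REML path agrees with closed-form
  one-way ANOVA estimators to well under 1%.
- Significance of random terms is assessed by likelihood-ratio tests
  against a 50:50 χ²₀/χ²₁ mixture, appropriate for a variance tested on
  its boundary.
- The optional "number of AMS visits" random term is implemented as a
  variance component within cow (`visit_count_re=True`), because MixedLM
  does not fit truly crossed random effects; it is off by default.

**Repeatability.** Within a year, R = σ²_cow/(σ²_cow+σ²_ε) on daily
phenotypes. `repeatability(vc, n_aggregated=n)` additionally reports the
repeatability of an n-day mean (residual shrunk by n) — the reading
under which published repeatabilities of period-averaged emissions
exceed the day-level variance ratio.

**Between years.** Daily data are first collapsed to cow-year period
means (the two-year model is indexed by year and cow), then modelled
with cow as the random intercept and year, EDMI, ECM and parity as fixed
effects; R₂ = σ²_cow/(σ²_cow+σ²_ε) measures the variance share the
animal carries across years. The literal alternative — year as the
grouping factor — is available via `mode="year-random"` but is not the
default, since a two-level grouping factor barely identifies a variance
component.

**Diurnal profile.** Hourly emission (L/h = visit ratio × daily CO₂/24)
is modelled with hour-of-day as a 24-level fixed factor, the same
covariates, and a cow random intercept; adjusted hourly means are
fixed-effect predictions at average covariates with delta-method
standard errors. Hours aggregate into night (0000–0600), morning
(0601–1200), afternoon (1201–1800) and evening (1801–2359); interval
means are equal-weight averages of hourly predictions and all pairwise
differences are Wald-tested.

**Levels of variation.** The pooled CV (sd/mean, ddof 1) is computed
over all units at each aggregation level; at the period level the units
are the cow period means, and herd precision is 2·CV/√n_cows — the
half-width, in percent of the mean, of an approximate 95% interval for
the herd mean. With the often-quoted period CV of 10.2% over 21 cows
this gives 4.5%.

## Synthetic data

The generator emulates the study conditions: 21 cows (14 primiparous,
deterministic split for test stability) measured 7 days, BW 619 ± 14.2
kg, milk 29.1 ± 6.5 kg/day (year 2: 33.4 ± 6.0), barn background
23.2/495.8 ppm CH₄/CO₂ (year 2: 25.8/625.5), 15-s sampling, visit counts
a truncated Poisson on {1..4} with mean 2.54. The ratio is hierarchical
log-normal — cow effect CV 8.4%, cow-day effect CV 15.9% (the year-1
ratio CVs), log-scale σ² = ln(1+cv²) with −σ²/2 mean offsets so every
effect has mean exactly 1 — times a unit-mean cosine diurnal factor with
trough at 04:00 (amplitude 0.10, a modest night-time depression).

Values the study context does not fix were chosen once as
field-realistic: breath-plume CO₂ excess 3000 ppm with 30% log-normal
sample noise (well above the 400-ppm filter; background samples carry
a tenth of that noise), visit duration 4–8 min, milk fat 4.5 ± 0.5% and
protein 3.4 ± 0.25% (back-solved so ECM/milk ≈ 30.8/29.1), herd TMR 15
kg DM/day with concentrate 6 ± 1.5 kg DM/day, pregnancy uniform on
0–200 days. In two-year mode, cow log-effects are bivariate normal with
configurable correlation (default 0.7); cows gain ~15 kg and milk is
redrawn at the year-2 mean with correlation 0.6 to year 1.

CO₂ plume noise cancels exactly in the sample ratio (both gases share
the plume), so ratio noise comes from the independent CH₄-side
multiplicative term — mirroring why the ratio method is robust to
dilution. Day-level estimated ratios therefore carry the configured
within-cow CV plus ~4% measurement noise (sample noise averaged over
~60 samples/day) plus ~4% from the diurnal factor sampled at 2–3 visit
hours; recovered CV_wc on simulated campaigns runs ~1–1.5 points above
the configured 16%, and day-level R correspondingly a little below the
latent 0.24. Parameter-recovery tests use bands that account for this.

What the generator does **not** emulate: eructation spike structure and
within-visit autocorrelation (samples are conditionally independent
given the cow-day ratio), plume dispersion physics, behavioural
perturbations (lameness, oestrus), drifts in instrument calibration, or
feed-driven changes in the ratio. Passing recovery tests therefore show
the estimation chain is consistent with its own generative assumptions,
not that those assumptions exhaust real barn data.

## Determinism

Every stochastic stage derives its generator from the configured seed
via `SeedSequence`; identical configs give byte-identical CSV outputs.
The run manifest records config, version, input checksums and row
bookkeeping (read = kept + filtered at the filter stage); its
`generated_at` wall-clock field is the one item excluded from
byte-identity comparisons.

## Problem sizes

Default analyses and tests run at the study design size (21 × 7);
Monte-Carlo recovery suites use 50 cows × 20 days × 10 seeds, which
bounds the between-cow CV's own sampling noise at roughly 10% relative
and keeps the whole suite under a minute of model fitting.

## Known limitations

- MixedLM boundary fits (σ²_cow → 0) are reported with a warning rather
  than refused; small herds (≈12 cows) regularly produce them for the
  ratio response, where the between-cow signal is weakest.
- The stepwise procedure tests terms by Wald p-values, not exact
  F-ratios with Satterthwaite degrees of freedom; at the row counts
  involved (≥100) the difference is negligible.
- `estimated_dmi` treats herd TMR intake as a constant; individual TMR
  intake is unobservable at an AMS and the reconstruction inherits that
  limit.
- Standardization slopes are per-year OLS on cow means; no shrinkage is
  applied, so with few cows the adjusted correlations are noisier than
  the actual ones.
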