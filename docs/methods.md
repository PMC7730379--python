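# Methods

## Model and assumptions

`spotsim` simulates urinary biomonitoring of a non-persistent chemical with
a one-compartment, first-order absorption/elimination model. Exposure is
oral only; dermal and inhalation routes, multi-compartment kinetics,
enterohepatic recirculation and saturable elimination are out of scope. The
population is adult: the synthetic urination schedules emulate adult diary
data and the results should not be extrapolated to infants or children.

Internal amount is evaluated analytically by superposing the Bateman
solution of each dose event rather than stepping an ODE solver. This is
exact for the model, removes integration error from every downstream
statistic, and keeps a 3000-individual run in the low seconds on one core;
the test suite retains an independent numerical oracle (`scipy.solve_ivp`
for the amount curve, adaptive quadrature for cumulative excretion, 0.01-h
trapezoids for the AUC) and requires agreement to 1e-4 relative or better.

The volume of distribution is fixed at 1, so "amount" and "concentration"
coincide in arbitrary units. Doses have population geometric mean 1. Both
choices are inconsequential: R², rank-based classification and the
log-scale ICC are invariant to any fixed multiplicative rescaling of doses
or concentrations. For the same reason the fraction of elimination excreted
in urine as the measured analyte (`fraction_excreted`, default 1) does not
move the reliability surfaces; it exists so mass-balance checks are
explicit.

Bladder accounting: the analyte mass appearing in a void is the cumulative
urinary excretion since the previous void; the first void of the simulation
drains from t = 0. Splitting an inter-void interval therefore conserves
excreted mass exactly, which the property tests verify.

The degenerate case ka = ke is rejected at parameter construction rather
than handled by the limiting form: it is a measure-zero configuration and a
clear error beats silent special-casing. Since person-level half-lives are
sampled, the configuration also requires the absorption half-life to be
shorter than the population elimination half-life.

## Key parameters

| parameter | units | default | note |
|---|---|---|---|
| biological_half_life | h | required | elimination half-life of the analyte |
| half_life_gsd | — | 1.3 | between-person spread of half-life |
| absorption_half_life | h | 0.4 | oral absorption, shared by all individuals |
| within_gsd / between_gsd | — | 3 / 2 | log-normal exposure variability |
| exposure_pattern | — | once_random | 1–3 events/day, random or fixed slots |
| window_days / max_samples | d / — | 7 / 7 | one sample per day at most |
| sample_timing | — | random_void | or first morning/evening void, whole-day composite |
| standardization | — | none | creatinine or specific-gravity adjustment |
| n_individuals | — | 3000 | population size |
| accumulation_days | d | max(14, 7·t½/24) | run-in before the window; taken as the exact value, no rounding to whole days, then ceiled only for the day grid |
| seed | — | 1 | root of all RNG substreams |

The default within/between GSDs (3 and 2) describe a typical non-persistent
chemical scenario with strong day-to-day and moderate person-to-person
exposure variability; both should be replaced by chemical-specific values
when available, as should the half-life defaults.

Exposure events occur on every simulated day, accumulation period included —
otherwise no steady state would be reached before sampling. Time-of-day
windows are morning 07:00–10:00, afternoon 12:00–15:00, evening 18:00–22:00,
"random" uniform over waking hours 07:00–23:00 (all configurable). Random
within-day times are drawn independently and sorted; coincident times are
re-drawn. Half-life variability applies to elimination only.

## Synthetic urination schedules

Void-level urine data are generated, not measured. The default bank of 8
templates × 6 day patterns emulates a diary study of eight adults over six
days: per day a void count uniform on {4..9}; a 24-h volume log-normal
(GM 1.5 L, GSD 1.4) split across voids by a symmetric Dirichlet
(concentration 4) with double weight on the first, overnight void; a
per-template daily creatinine excretion normal(1.2, 0.25) g/day truncated
above 0.4; per-void creatinine = excretion accrued since the previous void
(the first void pools the overnight interval, computed self-consistently
for a repeating day so each day's creatinine mass balances exactly) divided
by volume; specific gravity = 1 + 0.0075·(creatinine g/L)/0.45, clipped to
[1.002, 1.035], i.e. SG excess proportional to urine concentration.

Each individual keeps one uniformly chosen template for the whole run and
draws one of its day patterns per simulated day *with replacement*. What
the generator does **not** model: fluid-intake feedback, circadian GFR
variation, correlated consecutive days, children's voiding. Tests passing
on these schedules show the statistics behave correctly on realistic
*marginal* distributions of volume, frequency and dilution; they cannot
certify behaviour on features the generator lacks. Real diary data in the
documented CSV format can replace the bank (`load_schedules` /
`--schedules`).

## Sampling and pooling

Sampling days are spread evenly over the window
(`round(j·(D−1)/(m−1))`; a single sample lands mid-window); uniform-random
days are a config option. Pools are nested — size n uses the first n
sampling days chronologically — so the reliability-versus-n curve reflects
*adding* samples. Pooling is equal-volume: the pooled concentration is the
unweighted mean regardless of void volumes. "First evening void" is the
first void at or after 18:00, falling back to the day's last void.

The whole-day composite is the concentration a laboratory would measure on
a pooled 24-h collection: Σ(c·v)/Σ(v) raw; Σ(c·v)/Σ(cr·v) (analyte mass per
gram creatinine of the pool) under creatinine standardization; the raw
composite rescaled by the pool's volume-weighted SG under specific-gravity
standardization. For spot schemes the standardization applies per void:
c/cr, or c·(SG_ref−1)/(SG−1) with SG_ref = 1.020.

## Reliability statistics

Natural logs throughout (all three statistics are base-invariant). R² is
the squared Pearson correlation of log AUC and log pooled concentration —
identical to the regression R² in either direction, so the choice of
response is cosmetic. Quantile groups are rank-based equal-count cuts
(remainder to the lower groups, ties broken by stable individual index),
deterministic under ties. The ICC is the one-way random-effects ANOVA
estimator (MSB − MSW)/(MSB + (k−1)·MSW) on the k collected log
concentrations at the configured timing scheme; negative estimates are
clipped to 0 with a warning, the raw value is retained. Computing the ICC
on logs is the standard choice for log-normal biomarkers but is a
comparability caveat against tools that use raw concentrations. Zero
variance makes R² undefined for that n (reported missing with a warning);
non-positive AUCs or concentrations raise an error pointing at the
accumulation period / exposure pattern.

## Determinism and numerics

All draws flow from one root seed through named `SeedSequence` substreams:
the template bank at (seed, 0), sampling-day placement at (seed, 3), and
individual i's parameters/exposure/schedule/sampling at (seed, 1, i, stage).
Changing `n_individuals` therefore never perturbs earlier individuals'
draws. Output CSVs are written with fixed formatting; identical config and
seed reproduce them bitwise.

## Design choices made where the design was open

* **Null classification baseline.** With between-person GSD 1 *and*
  within-person GSD 1, everyone shares the same dose sequence and the AUC
  ranking is driven solely by the sampled half-life. A whole-day composite
  measures the day's excreted mass, which at steady state equals the daily
  dose independent of half-life, so the urinary ranking carries no signal
  and classification sits at the 1/3 and 1/4 chance levels. A single random
  *void*, by contrast, genuinely correlates with half-life (short
  half-lives concentrate the dose into a few post-dose voids), which is a
  feature of the model, not noise.
* **High-ICC limit.** Removing within-person variability (within GSD 1,
  half-life GSD 1, fixed daytime dose slots) and measuring whole-day
  creatinine-standardized composites leaves overnight carry-over as the
  only within-person noise; the single-sample ICC then approaches 1.
* **Accumulation floor.** The 14-day floor applies to the exact
  7-half-life value without rounding to whole days.
* **Config dialect.** YAML only; JSON files are rejected with a pointer to
  YAML so that a run is reproducible from exactly one documented format.

## Problem sizes used by the test suite

Monte Carlo checks use the sizes at which their expectations are sharp:
10 000 draws for log-normal moment recovery, ~1000 synthetic schedule days
for the distributional envelope, 500 individuals for the ICC variance
limits, 3000 individuals for the chance-baseline and information-gain
scenarios (the latter over 20 seeds, 30 samples over a 30-day window).
The full default scenario (3000 individuals, 14-day accumulation + 7-day
window) runs in a few seconds on one core.

## Known limitations

Single compartment and oral route only; equal-volume pooling only; at most
one sample per day per scheme; synthetic (not measured) urination
schedules; no autocorrelated or seasonal exposure; ICC reported for the
log scale only.
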