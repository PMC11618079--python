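# Methods

This note records the models implemented in `partmig`, the defaults and why
they were chosen, and the boundaries of what the synthetic experiments can
show.

## Synthetic population generator

Each bird's series lives on a 30-minute grid over one non-breeding season
(default 1 September – 30 April). Day and night are split by a
solar-declination daylength formula at the configured latitude (default
47.78° N) with solar noon pinned to 12:00; this avoids an ephemeris
dependency and is accurate to well under one grid step at mid latitudes.

Heart rate (bpm) and body temperature (°C) follow

```
f_H(t) = [mu_phase + b_i + e(t)] · (1 − ramp(t)) + flight(t) + recovery(t)
T_b(t) =  mu_phase + c_i + u(t) − winter_decline(t) + flight_Tb(t)
```

with day/night phase means, normal per-bird intercepts, and stationary AR(1)
residuals. Defaults (all config-exposed, none hard-coded downstream):

| quantity | default | note |
|---|---|---|
| nocturnal / diurnal f_H mean | 374 / 470 bpm | the nocturnal level is back-derived from the flight elevation being a ~53% increase of 199 bpm; baseline means are not themselves reported field values |
| f_H individual sd / AR1 φ / noise sd | 15 bpm / 0.6 / 12 bpm | typical biologging repeatability structure |
| nocturnal / diurnal T_b mean | 39.6 / 41.3 °C | passerine circadian range |
| T_b individual sd / noise sd | 0.25 / 0.15 °C | sensor pre-calibrated to ±0.2 °C |
| pre-departure ramp | starts 28 d before fall departure, linear to −19.5% | nocturnal, multiplicative, migrants only |
| flight elevations | +199 bpm, +1.23 °C | applied to the first `night_flight_fraction` (default 0.7) of each flight night's intervals |
| post-arrival recovery | −36 bpm nocturnally for 8 d after winter arrival | |
| resident winter T_b decline | 0.18 °C during the calendar core winter | makes the migrant−resident winter T_b contrast +0.18 °C by construction |
| wintering T_a offset | +5.7 °C | with q25/q75 series bracketing the mean by ±2 °C |
| journeys | departure windows 5 Oct–10 Nov and 1–20 Mar; flight nights 1–9, mean 4; stopover gaps Poisson(1.5) | fall journeys complete before the core winter begins |

There is deliberately **no** f_H strategy term outside the ramp, flight and
recovery effects, so the true winter heart-rate contrast is zero — the null
the statistics must not reject.

Measurement corruption: each record draws one of four quality-index classes
(probabilities 0.4/0.3/0.2/0.1) and is corrupted with class probability
0.02/0.08/0.20/0.50 by multiplying the true bpm by 0.5 or 2 (missed or
double-counted beats — the two characteristic failure modes of on-board ECG
peak detection). Every 120th record per logger (60 h) keeps the true value,
emulating the raw-ECG verification subsample. T_b is never corrupted.

What the generator does **not** emulate: weather-driven short-term
covariation of f_H/T_b with T_a, individual differences in effect sizes,
logger drift or dropout, and partial nights of mixed flight/stopover.
Passing tests therefore demonstrate that the pipeline recovers effects of
the configured form and magnitude under realistic noise, not that it would
be robust to every failure mode of field data.

## Quality control

Error rate per (logger, QI class) = fraction of truth subsamples with
relative deviation above `mismatch_tolerance` (default 0.10 — the notion of
a "wrong" logger value needs a threshold; the ×0.5/×2 kernel makes the
calibration insensitive to its exact value). Rates from fewer than 5 truth
samples are undefined, and undefined is not zero: such classes are dropped.
Filtering keeps classes with rate < 0.15 and f_H within 60–800 bpm
(plausibility bounds; config-exposed). T_b rows are retained independently
of the f_H filter.

## Migration classification

Features per measurement: f_H, T_b, logger identity (integer category),
per-individual z-scores and deviations from the individual mean, and the
proportional T_b change versus the previous interval (the alternative —
change versus the nightly minimum — is config-switchable). Individual
scaling statistics are computed on each bird's first 30 days only, so flight
nights cannot leak into the standardization.

The classifier is sklearn's `GradientBoostingClassifier` with 500 trees,
depth 3, learning rate 0.05 (classic boosted-regression-tree defaults);
training uses a by-bird split so evaluation is held-out at the individual
level. A night is called *flight* when ≥ 25% of its flight-labelled
intervals are positive (exposed as `night_fraction`); events follow the
rule: first flight night = departure, morning after the last flight night of
a journey = arrival, stationary nights strictly between = stopovers, with
fall and spring journeys split at 1 February.

## Pairing and statistics

Within every (timestamp, sex) cell, residents are matched one-to-one to
migrants by a seeded random permutation, so each resident measurement is
referenced at most once across the whole dataset (hard-asserted) and
leftover residents are unused. Autocorrelation is thinned by removing
exactly `round(0.30·n)` records per bird.

Strategy contrasts are fitted per season × day-phase cell with statsmodels
`MixedLM`: `response ~ strategy + sex`, a per-bird random intercept and a
date variance component; p-values are Bonferroni-corrected across cells.
Interval quantiles use a *t* distribution with (number of birds − 2)
degrees of freedom rather than normal quantiles: the contrast's uncertainty
is dominated by a modest number of bird intercepts, and Wald-z intervals
under-cover at these group counts.

Event-centred smooths use a B-spline basis (default rank 8, cubic) inside
`MixedLM` with a per-bird random intercept. The basis rank plays the role of
the smoothing parameter; a dedicated penalized-GAM backend with random
effects is not used because no available backend offers both, and at these
ranks the difference is immaterial for the day-scale trends of interest.
Between-strategy significance is read as the maximal day ranges where the
two 95% confidence bands do not overlap — deliberately conservative
relative to an interaction test.

## Experienced temperature and scenarios

Hourly ambient series are interpolated linearly to the 30-min grid. A
migrant with n fall flight nights experiences
`(1 − w)·breeding + w·wintering` with w stepping to k/n at the **end** of
the k-th flight night (the bird completes a leg before its daytime
temperature changes); spring reverses symmetrically. Scenario grid: resident
offsets {0, +1, +2} °C applied only inside the migrant-absence window
(earliest fall departure to latest spring arrival) × wintering quantile
series {mean, q25, q75}.

## Heat balance

The bird is a prolate ellipsoid (elongation 2) of density 1000 kg/m³ wrapped
in a flesh shell (5 mm, k = 0.5 W/m·K) and a plumage layer (6 mm,
k = 0.027 W/m·K ≈ still air). Surface areas use Thomsen's p = 1.6075
approximation (≤ ~1% error); the convective characteristic dimension is the
equivalent-sphere diameter of the feathered body. Convection follows
Nu = 0.37·Re^0.6 with a free-convection floor Nu = 2; radiation is
linearized as h_rad = 4εσT_film³ with the film temperature fixed at the
midpoint of T_b and T_a (no surface-temperature iteration — the bisection
oracle in the tests bounds the closed form against an independent solve of
the same balance to 10⁻⁶ W). Basal power uses a passerine allometry
(6.25·M^0.724 W ≈ 1.0 W at 90 g); total power is floored at basal
(thermoneutral convention) and the ledger always reports both total and
above-basal columns. Strategy differences are computed on the total,
matching an expenditure framing.

Omissions relative to full endotherm microclimate models: no evaporative or
respiratory heat loss (cold-season regime), no solar radiation, no posture,
huddling or microhabitat selection, no torpor. The default parameterization
yields a whole-body conductance near 0.05 W/°C (sheltered bird in light
wind); `pipeline.winter_exposed_thermo_params` provides an open-habitat
variant (4 m/s wind, wind-penetrated plumage with effective
k = 0.09 W/m·K) with conductance around 0.14 W/°C, the scale at which
field energetic models for open winter habitat typically operate.

## Budget accounting

Flight energy per migrant = 52.6·M^0.74 W × classified flight seconds at
30-min resolution. Because quality filtering removes intervals, the flight
fraction observed on surviving intervals of a flight night is rescaled to
the full night length taken from the (unfiltered) T_b grid; otherwise QC
losses would bias flight duration low by the discard rate. The headline
fraction uses the population-mean flight energy over the central scenario's
savings, with min/max over the scenario grid; scenarios with non-positive
savings are flagged and excluded from the range.

The end-to-end benchmark (`pipeline.budget_benchmark`) fixes the *true*
flight-cost/savings ratio at 7% by calibrating the per-night flight duration
against the ground-truth savings (flight energy is linear in duration;
savings do not depend on it), using short journeys (1–2 flight nights per
season) and the open-habitat thermal parameterization so the calibrated
flight blocks stay well above the night-call detection fraction. The
pipeline's estimate of the same ratio — classifier-derived flights,
event-derived experienced temperatures — is then compared against that
truth.

## Problem sizes

The shipped tests run populations of 2–20 birds over seasons of 40–240
days (10⁴–10⁵ intervals), 50 replicates for null-coverage checks, and
100-point grids for oracle equivalence; these sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the suite quick to run.

## Known limitations

- The heat balance is one-node and steady-state per interval; transient heat
  storage in the body is ignored.
- Event-centred smooths omit a date random factor (bird intercepts only).
- The generator's effects are additive/multiplicative and homogeneous across
  birds; interaction structure in real data may be richer.
- Flight-duration resolution is the 30-min measurement interval.
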