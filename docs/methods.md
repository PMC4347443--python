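# Methods

## The parallel chilling–forcing model

Many temperate woody plants need winter chilling before spring warmth can
force budburst. `chillforce` implements the *parallel* (concurrent) form
of this dormancy model: chilling and forcing accumulate simultaneously
through the dormant season, and budburst becomes possible as soon as the
accumulated pair crosses a species-specific tradeoff curve.

Each hour of air temperature `T` contributes to two cumulative sums,

    chilling units: C(t) = Σ e_c(T_i) · Δt_i
    forcing units:  F(t) = Σ e_f(T_i) · Δt_i,

where `e_c`, `e_f` ∈ [0, 1] are temperature-effectiveness weights and
`Δt_i` the record step in hours, so units are effectiveness-weighted
hours. Accumulation starts on a configurable season-start date (default
November 1) and continues to the end of the series — chilling has **no
spring cutoff**, because late-season cool hours still reduce the forcing
requirement.

The tradeoff ("possibility line") is

    F_req(C) = a0 + exp(a1 + a2·C),    a0 ≥ 0, a2 ≤ 0,

the forcing required for 50% of a population to burst bud after receiving
`C` chilling units: a declining exponential approaching the asymptote
`a0`. The predicate `F ≥ F_req(C)` (boundary inclusive, so crossings are
deterministic) defines where budburst is possible. Because `C` and `F`
are nondecreasing in time and `F_req` nonincreasing in `C`, the first
crossing is unique: once possible, always possible. Species that cannot
burst normally without chilling carry an obligate threshold `c_min`;
below it `F_req = +∞`.

## Effectiveness curves

The true effectiveness functions are known only up to their qualitative
shape, so both curves are user-configurable piecewise-linear knot lists
(`load_curves`), with packaged defaults that encode:

* **chilling** — zero at or below −5 °C, a small positive value just
  below freezing, a peak of 1 at 2–4 °C, a decline to a small positive
  value above 10 °C (warm hours still chill, weakly) and zero from 16 °C;
* **forcing** — a sigmoid from 0 below ~0 °C to ~1 by 25 °C.

The defaults are a documented approximation, not calibrated data; every
downstream computation is exact given a curve, and all analyses accept
replacement curves. Interpolation is linear between knots (the simplest
continuous choice); outside the knot span a constant (default 0) applies.

## Unit accumulation conventions

* A record's timestamp marks the **end** of its step interval; units at
  time `t` sum records with `season_start < t_rec ≤ t`. This makes the
  trajectory exactly zero at the season start.
* Units are always hours-based regardless of the record step; 30-min
  records are supported and reproduce hourly totals exactly on
  piecewise-constant input.
* Timestamps are naive local standard time (weather-station convention,
  no DST).
* Gaps up to `max_gap` (default 72 h) are filled by linear interpolation
  in time; longer gaps are a hard error naming the gap, since silently
  bridging a long outage would corrupt both unit sums.

## 50%-budburst points and line fitting

Seedlings are checked on discrete dates; a seedling counts as burst once
bud scales part (the status is absorbing), and seedlings re-coded as
abnormal (scales parted but no elongation) count as never burst. The 50%
date is the first check at which the burst fraction reaches 0.5, with
linear interpolation between the flanking checks; the treatment's
(chilling, forcing) point is the trajectory value at that date.
Treatments whose final fraction stays below 0.5 yield constraint points
(`reached_50=False`).

Lines are fit by constrained nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with bounds
`a0 ≥ 0`, `a2 ≤ 0`; starting values come from a log-linear regression of
the excess forcing over `0.8·min(F)`. Options:

* `asymmetric=True` doubles the weight of negative residuals, pushing the
  line toward the lower envelope of the point cloud;
* `obligate=True` sets `c_min = c_min_factor · min(C among reached
  points)` (default factor 0.5). The exponential form cannot literally
  become vertical at low chilling, so the obligate behaviour is encoded
  as this hard threshold rather than by distorting the parametric fit.
  Constraint points that nevertheless lie above the fitted line trigger a
  warning rather than an error.

## Prediction and warming projection

`predict_budburst_date` returns the first record at which the possibility
predicate holds, or `None` if it never does within the season.
Multi-season means average the predicted **day-of-year** (1 = Jan 1 of
the calendar year following the season start; a December burst maps to
values ≤ 0 on the same continuous axis, keeping averages well-defined).
Seasons with no predicted budburst are excluded from the mean and
reported as a failure count.

Warming scenarios add twelve monthly mean-temperature deltas to the
contemporary hourly records (attribution by each record's calendar
month); per-month means shift by exactly the delta. The change in
budburst date is `future − current` of the multi-season means, negative
meaning earlier. Batch projection isolates per-station failures in a
status column. Spatial interpolation of the per-station table is left to
external mappers.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis assumes:

* **Ambient climate** — hourly temperature = annual cosine (minimum on
  `coldest_doy`) + diurnal cosine (peak mid-afternoon) + stationary AR(1)
  noise. The default (`olympia_ambient`) has annual mean 9.14 °C and
  amplitude 7 °C, calibrated analytically so the November–March mean is
  4.0 °C — the mild maritime winter of the trial setting. (The
  calibration is deterministic: the diurnal term and noise average to
  zero, so the winter mean follows from integrating the annual cosine.)
* **Treatment schedules** — weekly weekday patterns over four
  environments: greenhouse = `max(ambient, 15 °C)` (a *minimum* setpoint,
  so the all-greenhouse regime averages ≈15.0 °C in winter), growth
  chamber = 18 °C fixed, ambient = the outdoor draw, cold = the outdoor
  draw −1.5 °C (a colder site; winter mean ≈2.5 °C). The packaged
  regimes range from 7 d/week greenhouse ("warm") to all-outdoor
  ("ambient"/"cold"), plus six-week chamber-forcing windows.
* **Seedling heterogeneity** — seedling *i* multiplies its forcing
  requirement by `m_i = exp(N(0, σ))` (lognormal keeps requirements
  positive and symmetric on the log scale; default σ = 0.05). Its burst
  moment is the first record with `F ≥ m_i · F_req(C)`; observations are
  emitted only on weekly check dates (configurable).
* **Station gradients** — annual means evenly spaced across the
  requested range, with the seasonal amplitude co-varying from 3.5 °C at
  the mild end to 8.5 °C at the cold end. Mild-winter coastal sites are
  maritime (damped annual cycle) while cold sites are montane or
  continental; without this co-variation a "mild" station would still
  have cold continental winters and the later-budburst response to
  warming would not be representable. Eight seasons per station, shared
  monthly deltas, elevation decreasing with annual mean.

The reference line used across the simulation studies is
`a0=300, a1=8.5, a2=−0.0012, c_min=300` (effectiveness-weighted hours),
chosen once so that the requirement spans the unit scales the standard
regimes actually produce: ≈5200 forcing units at zero chilling, falling
to the 300-unit asymptote near 3600 chilling units, with the
all-greenhouse regime (≈270 chilling units/season) falling short of the
obligate threshold — so it never reaches 50% budburst, as observed for
obligate-chilling conifers held warm all winter.

What the synthetic data does **not** contain: weather fronts and synoptic
persistence beyond AR(1), photoperiod effects (the model is
temperature-only), frost damage or delayed treatment moves, soil
temperature for the cold regime, and between-lot or provenance
differences. Passing recovery tests therefore show the estimator is
consistent under the model's own assumptions, not that real trials are
free of these complications.

## Numerical choices

* All randomness flows from integer seeds through
  `numpy.random.SeedSequence` spawning, so every generator is
  reproducible and independent sub-streams never collide.
* The fit uses tight tolerances (`xtol=ftol=gtol=1e-14`) — the problems
  are tiny (3 parameters, a handful of points) so the extra iterations
  are free and noiseless recovery reaches ~1e-16 relative error.
* `exp` underflow at high chilling is harmless and silenced; overflowing
  trial parameters during fitting are mapped to a large finite residual.
* Ties at exactly a 0.5 burst fraction resolve to the earlier check.
* Serialized floats use 9 significant digits; CSV round trips preserve
  trajectories to ~1e-8 relative.

## Study sizes

The packaged analyses use 270-day seasons for trials, 300-day seasons for
stations, 24 seedlings × 5 regimes per trial replicate, 100 replicates
for recovery studies, and 20 stations × 8 seasons for the gradient
projection; these sizes give stable medians (recovery medians move by
<1 point between seeds) while each full study completes in seconds.

## Known limitations

* Air temperature is a surrogate for meristem temperature; no bud-level
  energy balance.
* The effectiveness-curve defaults are qualitative approximations; users
  with calibrated curves should supply them.
* `c_min` is a hard threshold tied to the sampled treatments, so its
  recovered value depends on which regimes reached 50% budburst.
* The fit reports residual diagnostics only — no confidence intervals on
  (a0, a1, a2).
* Multi-season means average day-of-year; no weighting by record
  completeness.
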