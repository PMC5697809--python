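# Methods

## Scope and data model

The package analyzes outgoing-call events only: one record per call with
caller id, callee id, a zone-local timestamp and a duration. Subscribers
carry age, gender and two residence proxies (postal-code centroid and
most-accessed cell tower). A subscriber is attributed to a city only when
all three distances — tower↔center, postal↔center (each < 15 km) and
tower↔postal (< 30 km) — hold, with strict inequalities; cities enter the
study only above 100,000 inhabitants (strictly greater, configurable).
Distances are great-circle on a 6371-km sphere.

City coordinates follow a masking convention for de-identified operator
data: a city's latitude is the center of a latitudinal band (φ ± dφ) and
its longitude is a signed offset θ from an arbitrary reference point in
the band (west negative). All solar computations therefore take a
relative longitude plus a configurable reference meridian; they depend
only on the sum, which is verified by a masking-invariance test.

Timestamps stay in official zone clock time everywhere except inside the
solar module. All of the analysis windows are clock times, so no UTC
conversion is ever applied to call data.

## Activity days and distributions

Calling activity is almost null around 04:00, which provides a natural
day boundary: an *activity day* runs from 04:00 to 03:59 of the next
calendar date and is indexed by the calendar day containing its 04:00
start. Times are *extended hours* in [4, 28). The first-call window is
[5, 16) and the last-call window [17, 28), each 11 h, half-open, and
disjoint by construction. A call at exactly 05:00 belongs to the morning
window; a call between 04:00 and 04:59 belongs to the *next* activity
day's early hours and can only appear in that day's statistics (this also
covers the occasional very-late-Friday morning tail without any special
casing).

Per city and day, three distributions are built by binning into 5-min
bins (default; matching the alignment grid step so shifts are whole-bin
moves): P_all over all calls on [4, 28), P_F over per-user first calls
and P_L over per-user last calls. Distributions normalize to 1 (checked
to 1e-9); empty inputs produce an all-zero distribution flagged by
`n_events == 0`. The daily mean first/last-call times t_F, t_L are means
of the raw per-user times; means of the binned distribution differ only
at sub-bin scale and are available through `mean_time`.

Distributions may be pooled per weekday across weeks (`per-weekday`
pooling, the CLI default) instead of kept per day. Calling timings differ
systematically across the week, so pooling never crosses weekday
boundaries. Pooling multiplies the per-distribution sample size by the
number of weeks, which matters for the alignment step below.

## Shift alignment by KL divergence

The delay between two cities' calling patterns is estimated by a grid
search: candidate shifts nΔ with −5 ≤ n ≤ 8 and Δ = 5 min. For each n the
candidate distribution is advanced by nΔ and compared to the reference
with D_KL(P, Q) = Σ P_i log(P_i/Q_i), P the reference. The minimizing nΔ
is the recovered delay; positive for a city whose activity runs later
(west of the reference). Ties break toward smallest |n|, then negative n.

Two numerical choices matter:

* **Smoothing.** Empty bins break D_KL; both distributions get an
  additive pseudocount of α = 0.5 per bin (on implied counts) and are
  renormalized. Configurable.
* **Edge handling.** Both distributions are observed through the same
  fixed 11-h window, so a candidate advanced by nΔ has *no data* in the
  trailing bins that rolled in from beyond the window edge. Scoring the
  reference's mass there against near-zero smoothed mass produces
  p·log(p/ε) edge artifacts that can dominate the divergence and bias the
  argmin toward zero even when the two shapes are plainly translated.
  The grid search therefore scores each shift on the *overlapping*
  support only, truncating and renormalizing both sides to it. The
  standalone `shift_distribution` operation keeps the simpler
  truncate-and-renormalize contract (drop shifted-out mass, renormalize),
  which is exact for its purpose of moving mass; a circular shift was
  rejected because the night window is not periodic.

Daily best shifts are averaged per weekday (population standard
deviation, n denominator); holidays can be excluded via a supplied
calendar — none is hardcoded, since the study region is masked. Per-day
alignment at ~1,000 users per city is noise-limited: the KL basin is
shallow relative to multinomial noise over 132 bins, and the grid argmin
is then pulled toward the grid's interior. Weekday pooling across weeks
(8 weeks ≈ 8,000 events per distribution) makes the basin sharp; the
band-level recovery tests run pooled.

## Solar ephemeris

Declination and the equation of time use Spencer's Fourier series in the
fractional year — accurate to a few tenths of a minute, sufficient for a
minutes-scale behavioural analysis (verified against an independent
NOAA Julian-century implementation to within ±2 min across 2007 at
37–43°N). Sun transit is 12:00 − EoT − lon/15 h plus the zone offset;
sunrise and sunset use the hour angle at zenith 90.833° (standard
refraction plus solar radius). Solar midnight is the midpoint of sunset
and the next day's sunrise, computed on the current day's clock offset so
the identity |solar midnight − (transit + 12 h)| < 1 min holds on every
study day, including DST transitions; both definitions are implemented
and the identity is a test property.

Clock rules default to a European UTC+1 zone with DST (+1 h) from day 84
(Mar 25, 2007) to day 301 (Oct 28, 2007); fully configurable. On this
clock the annual solar-midnight curve has interior minima near days 134
and 305 and an interior maximum near day 209 (equation-of-time extrema
interacting with the DST window), plus a genuine February maximum near
day 44. Extremum detection splits the daily curve at discontinuities
(|day-to-day jump| > 0.4 h, i.e. DST steps) and looks for local extrema
within continuous segments over a ±5-day neighbourhood, so DST steps are
never themselves reported as extrema.

## Band collapse and cohort metrics

Within a band, each city's timing series is advanced by its sun-transit
delay relative to the reference city (a city at −7.8° is advanced by
31.2 min), after which solar-entrained cities coincide; the band curve is
the unweighted mean across cities (no population weighting). The band
curves t̄_F(d), t̄_L(d) are tabulated against solar midnight and sunrise
of the reference location, with interior extrema annotated.

Cohort tables resolve t_F, t_L, T_LCA = (t_F + 24) − t_L and
t_mid = (t_L + t_F − 24)/2 per (age bin × gender × weekday). Age bins
default to 2-year bins over [18, 80]. t_L is kept on the 0–24+ clock of
its day (past-midnight values exceed 24), so the t_mid formula applies
verbatim without case splitting. A weekday-w row pairs the *nights* of
weekday w with the mornings of weekday w+1 — the morning that closes that
night's rest period. Monday–Thursday nights can optionally be pooled
(off by default). Cohorts whose smaller window has fewer than 50 events
(configurable) are suppressed rather than reported noisily.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with every injected parameter recorded in a separate truth table (never
inside the CDR itself).

* **Daily intensity.** λ(t) on [4, 28) is a flat floor plus two truncated
  Gaussians renormalized on the window (an interval, not a circle, hence
  no circular distribution). Defaults: morning bump centered 12.0 h,
  σ = 1.8 h, 45% of call mass; evening bump centered 20.0 h, σ = 1.4 h,
  55%; floor at 1% of the peak rate. These widths give the observed
  qualitative shape of urban calling activity: a pronounced afternoon
  trough between 15:00 and 17:00, near-null activity around 04:00, and
  sharp, well-defined maxima in the first/last-call distributions. Mean
  4.0 calls per user-day; λ is scaled so its closed-form integral equals
  that mean exactly (the analytic integral and CDF also serve as test
  oracles).
* **Phases.** Each city's whole profile is rigidly shifted by its
  sun-transit delay, 4 min per degree of relative longitude (west later);
  a seasonal term adds `amplitude × (solar midnight − annual mean)` in
  clock time (default amplitude 0.3, so the summer–winter swing of t̄_L
  stays under an hour while the sunset swing is ≈ 3 h — the amplitude
  compression seen between cue and response); weekday offsets delay
  Friday and Saturday nights by 15 and 20 min.
* **Cohorts.** Default cohorts inject a 30-min younger-later mid-sleep
  gap, a 12-min female-later gap, and a 3-h longer rest period for the
  older cohorts. Cohort offsets are *defined on the windowed
  observables*: the generator root-finds the two bump-center moves such
  that the model-implied window-restricted mean first/last-call times
  move by exactly t_mid ± T_LCA/2 relative to the offset-free profile.
  A naive rigid shift is attenuated several percent by the fixed 11-h
  windows, which would make "recover the injected offset" ill-posed.
  Calibration happens once per cohort at zero context shift, so all
  cities share identical cohort geometry and differ only by exact rigid
  translations — the structure the alignment step measures. At nonzero
  seasonal/weekday context the calibration carries a second-order
  (≈1 min) residual.
* **Sampling.** Calls are an inhomogeneous Poisson process. The per-user
  API samples by thinning against the profile maximum; the bulk path
  draws per-user Poisson counts and positions via the inverse CDF on a
  1-min grid. One RNG substream per (city, cohort, day) is derived from
  the master seed through `SeedSequence` spawn keys, so generation is
  deterministic and independent of iteration order. Durations are
  exponential (mean 120 s) and callee ids uniform — no social-network
  topology is modelled.
* **Placement.** Subscribers are placed within ~5 km of their city
  center so the residence rules pass; deliberately misplaced subscribers
  (tower ~18 km out) can be added for filter tests.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: burstiness and inter-call correlation
within a user-day, heavy-tailed user activity levels, social-network
call structure, holidays and special events, weather, or any feedback
between daylight duration and call volume. It emulates phases, not
amplitude seasonality.

## Problem sizes

The end-to-end recovery checks run at 5 cities × 1,000 users × 8 weeks
(band phase recovery, weekday-pooled) and 2,000 users per cohort × 8
weeks (cohort offsets, Tuesday nights), sizes at which the estimators'
sampling error is comfortably inside the assertion tolerances (one 5-min
grid step; 5 min for a 30-min mid-sleep gap; 10 min for a 3-h rest-period
gap; 3 min for a 12-min gender gap). The analytic solar checks cover all
365 days of 2007 at the band latitudes.

## Known limitations

* The ephemeris is minutes-accurate by design (Spencer series, fixed
  civil zenith); it is not an astronomical library.
* Alignment resolution is bounded by the 5-min grid; fractional delays
  snap to the nearest step, and per-day (unpooled) alignment needs much
  larger per-day samples than per-weekday pooling to be unbiased.
* t_mid is a population proxy computed from calling activity; it is not
  a clinical mid-sleep measurement, and no individual-level chronotype
  classification is attempted.
* Window means are attenuated for distributions with appreciable mass at
  the window edges; the generator's calibrated injections account for
  this, but analyses of real data with very late first calls or very
  early last calls inherit the same censoring.
* The year model is a fixed 365-day (non-leap) study year with
  configurable DST days; the masked country's true holiday and DST
  calendar must be supplied by configuration.
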