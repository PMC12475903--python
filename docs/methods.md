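# Methods

This note records the scientific and numerical choices behind `grapecold`:
what each stage computes, the parameters that matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Data model and curation

Daily records are kept in °C as decimals; the tenths-of-a-degree integer
encoding of the GHCNd `.dly` format exists only at the file boundary.
During parsing, any non-blank quality flag invalidates the flagged value
(a conservative rule; archives flag values for many reasons and none are
trustworthy for modelling), a decoded temperature outside [−90, 70] °C is
rejected as implausible, and a day with tmax < tmin has both values blanked
and logged — such days are physically inconsistent and neither value can be
trusted.

Curation applies four screens. Geographic: 30° ≤ |latitude| ≤ 55°,
boundaries inclusive (the band covers cool-climate viticulture in both
hemispheres). Temporal: data before 1960-01-01 are discarded and stations
that ceased before then are dropped. Record length: the first-to-last span
of days with both extremes must reach 2 years (365 days per year). Quality:
each dormant season must have at least 220 days with both extremes.

Seasons run 1 September – 1 May in the north and 1 March – 1 November in
the south, closed at the start and open at the end (242–243 candidate days
in the north; leap days count). A season is labelled by the calendar year
of its start date.

The record-length screen is evaluated on the post-cutoff record, i.e. after
temporal truncation. Ordering it before truncation would make curation
non-idempotent: a station with a long pre-1960 record but under two
post-1960 years would pass once and fail on re-curation of its own output.
With this ordering, `curate(curate(X)) = curate(X)` holds exactly, which is
the property the pipeline relies on when curated archives are re-processed.

## Hourly reconstruction and thermal features

Chilling and heat accumulation are defined on hourly temperatures, which
must be reconstructed from daily extremes. The diurnal template is a sine
rise from the sunrise minimum to an afternoon maximum equal to the day's
tmax — T(h) = tmin + (tmax − tmin)·sin(π(h − sunrise)/(daylength + 4)) —
followed by a logarithmic overnight decline from the sunset temperature to
the next day's sunrise minimum. Sunrise/sunset come from the standard solar
declination formula (declination = −23.44°·cos(2π(doy + 10)/365)); the
scheme is refused poleward of 66.6° where polar day/night breaks it. Because
on-the-hour sampling would otherwise just miss the sine peak, the sampled
hour nearest the peak is pinned to tmax and the sunrise hour to tmin, so
daily extremes are recovered exactly — a contract the feature definitions
depend on. The contract here is the curve's qualitative shape and exact
recovery of the daily extremes, not bitwise agreement with any particular
published implementation.

Gaps of up to 3 consecutive missing days are linearly interpolated at the
daily level before reconstruction (nearest-value at season edges); a longer
gap invalidates the season for feature extraction even when the 220-day
screen passed, since accumulations would silently skip weather.

The accumulations, all cumulative from the season start and reported at
each day's end:

* **Utah chill units** — stepwise hourly weights: 0 at ≤ 1.4 °C, 0.5 in
  (1.4, 2.4], 1.0 in (2.4, 9.1], 0.5 in (9.1, 12.4], 0 in (12.4, 15.9],
  −0.5 in (15.9, 18], −1.0 above 18 °C.
* **North Carolina chill units** — piecewise-linear weight curve through
  the anchor points (1.6, 0), (7.2, 1.0), (13.0, 0.5), (16.5, 0),
  (19.0, −0.5), (20.7, −1.0), (23.3, −2.0), flat outside; optimum 1.0 at
  7.2 °C, negative above ~19 °C.
* **Chill hours (CU)** — count of hours in (0, 7.2] °C.
* **GDH** — Σ max(0, T − base) for bases 0, 4, 7 and 10 °C (linear form;
  the sine-weighted variant is deliberately not used, keeping the heat
  descriptor independent of the diurnal template's amplitude details).

All weight tables are configuration, so a user can substitute published
variants without code changes.

The EWMA blocks use spans 1–30 days with α = 2/(span+1), recursive form
initialized at the first value. The *reverse* EWMA of day t is the same
recursion run over the season-to-date prefix traversed from day t back to
the season start and evaluated at the start — equivalently
r_t = α·Σ_{j<t}(1−α)^j x_j + (1−α)^t x_t, computed with an O(n) prefix
recursion. Forward EWMAs weight the recent past (deacclimation-scale
memory); reverse EWMAs weight the season's beginning (establishment
conditions). Both coincide with explicit-weight sums to rounding error and
with each other on constant series.

The four daily descriptors are tmax, tmin, daily mean (tmax+tmin)/2 and
diurnal range — the natural closed set over daily extremes. days_in_season
counts days elapsed since the season start date, with the start day = 0,
anchored at each hemisphere's own start (1 Sep or 1 Mar). With the 54
cultivar indicators the vector is 4 + 7 + 30 + 30 + 54 + 1 = 126 columns,
asserted structurally on every emission.

The shipped 54-entry cultivar registry (21 *V. vinifera*, 33 hybrids) is a
synthetic stand-in built from real cool-climate cultivar names; any
user-supplied registry must also contain exactly 54 uniquely named entries
because the one-hot block size is part of the feature contract.

## LT50 regression and damage

The regressor is `sklearn` `HistGradientBoostingRegressor` (300 iterations,
learning rate 0.1, 31 leaf nodes, min 20 samples/leaf), trained on a seeded
90/10 split with the held-out RMSE recorded in the bundle metadata. The
train/predict surface is regressor-agnostic: any object with fit/predict
can be wrapped in a `ModelBundle`, whose recorded feature-name list is
enforced (order included) at prediction time. Predictions are clamped to
[−40, 0] °C — a physiological plausibility interval for bud LT50,
configurable.

Damage potential uses the logistic D = 100/(1 + exp(k(T_min − LT50))) with
k = ln(9)/2 ≈ 1.0986 per °C, derived analytically as the unique logistic
through the two anchors D(LT50+2) = 10 and D(LT50−2) = 90. Other symmetric
sigmoids satisfy the anchors too; the logistic is chosen for its closed
form and odds interpretation (odds of damage multiply by 9 per 2 °C of
additional cold). Damage is evaluated daily against the same day's minimum
temperature and same-day predicted LT50.

Feature importance is permutation-based: the mean held-out RMSE increase
over seeded shuffles of each column, run through the package's own clamped
prediction path. Note that a fitted tree ensemble places a few splits on
even pure-noise columns, so their importance hovers slightly above zero
(≲ 0.005 °C in the test fixtures) rather than at it.

## Climatology

Season summaries take the seasonal minimum temperature, the deepest
hardiness — read as the most negative LT50, i.e. the numeric minimum — and
the maximum daily damage potential. Window averages are arithmetic means
per station over the seasons present in each window; the default windows
1960–1979, 1980–1999 and 2000–2024 are intentionally unequal in width, and
because means are per-season this is harmless.

Gridding assigns each cell the unweighted mean of its k = 5 nearest
stations under great-circle (haversine) distance on a 0.5° grid by default;
k, resolution and the grid bounds are configuration, since no single choice
is canonical. Ties in distance are broken by station order, making the
estimate fully deterministic and exactly reproducible by a brute-force
distance sort. Cell values are therefore convex combinations of station
values and never extrapolate beyond their range.

The feasible-area fraction weights cells by cos(latitude) to approximate
area and counts cells with window-averaged damage strictly below the
threshold (default 20%). No land/sea or terrain mask is applied — the
statistic describes the modelled grid, not actual plantable land. Percent
change between windows is 100·(F − F_baseline)/F_baseline and is reported
as undefined when the baseline fraction is zero.

## Synthetic generators

Weather: daily mean = annual_mean − annual_amplitude·cos(2π(doy −
coldest_doy)/365) with coldest_doy = 15 (north) or 196 (south), plus AR(1)
noise (coefficient 0.7, innovation σ = 3 °C); tmax/tmin sit ±half the
diurnal range (8 °C) around the mean; days go missing independently with
probability 0.02. Defaults describe a cool-climate mid-latitude station
(mean 8 °C, amplitude 14 °C), giving winters cold enough to exercise
chilling and damage. The generator does **not** emulate station outages
(missingness is independent per day), weather fronts, heteroscedastic
observation error, or any real climate normal — passing tests show the
pipeline's operations are correct, not that the model is calibrated to
real vineyards.

Ground-truth LT50: truth = clamp(ceiling + (floor − ceiling)·A +
gain·H + offset, floor, ceiling), with ceiling −8 °C, floor −28 °C,
A = min(1, chill-hours/850) the normalized chilling status, and H the
7-day EWMA of daily GDH-base-10 increments. The chilling requirement of
850 h was set from the synthetic climate itself so that A saturates in
mid-December — mid-winter — which is what produces the U-shape's descending
arm in the right part of the season; the deacclimation gain of 0.25 °C per
smoothed degree-hour makes the spring arm rebound by several degrees before
1 May. Cultivar offsets (vinifera 0, hybrids −2 °C) are constrained
non-positive so the ceiling clamp never hides them. The heat term *raises*
LT50 — deacclimation is loss of hardiness — and only the observation noise
(σ = 1 °C by default) consumes the random seed; the noiseless truth is a
pure function of the feature table and the configuration. The truth is
deliberately expressible in the extracted features so that
surrogate-recovery experiments have a well-posed target: a trained
surrogate should approach the injected noise floor, and does so in the test
suite at n ≈ 2900 rows (two stations × three seasons × two cultivars) —
a problem size chosen to keep the full suite under a minute while leaving
the recovery bracket [0.8σ, 1.5σ] comfortably testable.

## Known limitations

* The hourly template ignores cloudiness, advection and elevation; it is a
  climatological idealization adequate for accumulation features only.
* The NC weight curve and the identity of the 7 cumulative/4 daily
  descriptors follow common published conventions but other variants exist;
  all are configurable.
* Reported model skill on synthetic truth says nothing about skill on real
  LT50 measurements, which carry late-season measurement ambiguities and
  site effects absent here.
* The feasible-area statistic has no land mask and inherits KNN's
  insensitivity to station density gradients.
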