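# Methods

## Model and procedure

The pipeline evaluates occupational heat-illness cases against three rule
systems: an estimated wet-bulb globe temperature (WBGT), calendar-day event
rules, and an exposure-limit table.

**WBGT estimation.** Direct WBGT measurement needs natural wet-bulb and
globe thermometers; station networks record only dry-bulb temperature and
relative humidity. The package therefore estimates the natural wet-bulb
temperature with Stull's empirical closed form and maps (Tw, Ta) to WBGT
with Park's quadratic regression (coefficients in the README). Two
implementation points matter:

- every `atan` operates in **radians** — this is what reproduces reference
  wet-bulb values such as Tw ≈ 13.70 °C at 20 °C / 50 % RH; degrees do not;
- the `atan(Ta + RH)` term sums unlike units (°C + %). That is how the
  regression was fitted and printed, and it is implemented literally; a
  "corrected" form would be a different regression.

Both fits carry a validity envelope, RH ∈ [5, 99] % and Ta ∈ [−20, 50] °C.
Outside it the estimate is still computed but flagged `valid=False` — never
clamped or dropped — because daily maxima taken downstream must see every
hour. The wet-bulb depression property (Tw ≤ Ta below saturation) holds on
the heat-stress operating region (verified on a 0.25° grid over
Ta ∈ [−10, 50], RH ∈ [5, 98.5]); the empirical form overshoots at exact
saturation and in the subfreezing dry corner (Ta ≲ −14 °C), both irrelevant
to summer exposure but covered by the flag.

**Event rules.** A heat wave is a maximal run of at least `min_run_days`
(default 2) consecutive calendar days with daily maximum dry-bulb
temperature at or above `threshold_c` (default 33 °C, inclusive: a
[33.0, 33.0] pair qualifies). A missing calendar day breaks a run —
conservative, and avoids inventing weather. A tropical night keeps its
night-window minimum **strictly** above 25 °C (25.0 exactly is not
tropical). The night window is half-open, 18:00 on the previous day to
09:00 on the labelled day, so the flag on a case's onset date describes the
night immediately before onset. A day's `tmax` uses whatever hours exist
(the maximum is robust to gaps); the night minimum requires ≥75 % of the
15 window hours, else the flag is *indeterminate* (`None`), which is
distinct from `False` and reported separately in summaries.

**Exposure limits.** The limit table is data, not code: one WBGT limit per
(acclimatization × metabolic-rate class) cell, validated for completeness,
for limits strictly decreasing with workload, and for unacclimatized limits
never above acclimatized ones. The packaged defaults are the ISO-style
screening values listed in the README. Exceedance is inclusive
(WBGTmax ≥ limit). Case workload maps heavy physical work → *high* and all
other outdoor manual work → *moderate* — outdoor labour is at least
moderate, and this mapping reproduces the reference cohort's 45/47
exceedance count. Per-case WBGTmax defaults to the onset calendar day's
maximum; `wbgt_window_days` widens the window backwards when an analysis
wants the maximum over the days preceding onset as well.

**Summaries.** Percentages are rounded half-up to one decimal at
presentation; no rounding happens inside computations. Ages bin to decades
[20, 30) … [70, 80). Indeterminate event flags count as `False` in the
proportions and are tallied separately.

## Parameters

| parameter | unit | default | why |
|---|---|---|---|
| `heat_wave.threshold_c` | °C | 33.0 | Korean advisory definition (daily max, inclusive) |
| `heat_wave.min_run_days` | days | 2 | same definition |
| `tropical_night.threshold_c` | °C | 25.0 | advisory definition, strict |
| `night_window` | hours | 18→09 | covers evening through sunrise; configurable since "nighttime" is not standardized |
| `night_min_coverage` | — | 0.75 | a night minimum from fewer hours is unreliable; indeterminate beats wrong |
| `wbgt_window_days` | days | 1 | onset-day exposure is the proximate one |
| limit table | °C | see README | ISO-style screening values; fully overridable via YAML |

## Synthetic data

The weather generator emulates summer urban hourly conditions: an
asymmetric sinusoidal diurnal cycle (minimum at 06:00, maximum at 15:00,
default mean 26 °C, amplitude 4 °C), declared heat-wave episodes that lift
the daily maximum to a target peak via a daytime-weighted elevation (so
night minima stay at the background trough), declared tropical nights
floored at 26 °C across their window, relative humidity anti-phased with
the temperature anomaly (base 70 %, swing 20 %, clipped to [5, 99]), and
optional Gaussian noise (default SD 0.3 °C). With `noise_sd=0` the series
is closed-form, which is what makes the exact event-recovery property
testable: the wbgt → events → flag chain returns precisely the declared
episode and night lists. The generator does not attempt meteorological
realism — no weather fronts, no humidity dynamics, no multi-station
structure — so passing tests demonstrate pipeline correctness, not forecast
skill on real station data.

The cohort generator draws independent Bernoulli risk flags, uniform
integer ages, and truncated-Gaussian WBGT maxima (bounds 18–38 °C). Its
defaults are the reference cohort's margins: prevalences 41/47 (heavy),
22/47 (unacclimatized), 29/47 (heat wave), 37/47 (tropical night); WBGT
mean 29.9 °C, SD 2.1 °C; ages 29–77. Real cohorts have correlated risk
factors; the independence assumption is deliberate — it is the null
structure parameter-recovery tests need.

Each generator consumes a single seeded NumPy `default_rng` stream; a fixed
seed gives a byte-identical CSV.

## Numerical and statistical choices

- **Formula equivalence** is asserted to 1e−9 °C against an independently
  coded `math`-module transcription at 1000 random in-envelope points —
  tight enough that any coefficient or unit slip fails, loose enough for
  vectorized-vs-scalar evaluation-order differences.
- **Parameter recovery** uses two-sided 99 % binomial intervals per seed.
  A correct generator still lands outside a 99 % interval for ~1 % of
  seeds, so across 20 fixed seeds the test permits up to 2 misses per
  prevalence — the 99.9th percentile of Binomial(20, 0.01) — a significance
  level derived from the nominal interval, not from observed runs.
- **Tie-breaks:** all threshold comparisons follow their rule's wording —
  heat-wave and limit thresholds inclusive, tropical-night strict.
- **Degenerate inputs:** empty series/cohorts raise, unordered timestamps
  raise, non-finite temperatures raise; out-of-envelope hours are flagged,
  not removed.
- Sample sizes in the stochastic tests (20 seeds × n = 1000, plus an
  n = 100 tier) were chosen to make the binomial intervals a few
  percentage points wide, which resolves prevalence errors of the size
  that would matter while keeping the whole suite fast.

## Known limitations

- The reference cohort's per-case ages bin to decades (2, 4, 14, 16, 9, 2);
  the aggregated age distribution quoted alongside the original case series
  is (3, 4, 13, 15, 10, 2). The two cannot both be right; the package ships
  the per-case table verbatim and treats it as authoritative, so summaries
  computed here reflect the former. All five headline proportions are
  unaffected.
- The exact limit-table values behind the original 45/47 exceedance count
  were not published; the packaged defaults are standard screening values
  that reproduce that count, validated in aggregate only, not per case.
- Estimated WBGT omits solar radiation and wind; it is a two-variable
  regression, not a physical model, and inherits that regression's bias
  outdoors in strong sun.
- The heat-wave flag requires the onset day itself to fall inside an
  episode; an onset the day after an episode ends counts as not exposed.
- No inferential statistics are computed — the analysis is descriptive
  (counts and proportions), matching its source design.
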