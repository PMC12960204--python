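# Methods

This note documents the models, conventions and numerical choices behind
`luxdose`, and what the synthetic cohort does and does not emulate.

## Solar geometry

Dawn and dusk are computed with the NOAA fractional-year solar position
series (equation of time and declination as truncated Fourier series in the
fractional year), solving cos h₀ = cos ζ /(cos φ cos δ) − tan φ tan δ for
the hour angle at zenith ζ = 90° + 6°. The crossing time is evaluated in
two passes (the second re-evaluates the series at the event time). Accuracy
is ±2–3 min against an independent Meeus-style ephemeris, which is ample:
downstream uses are day segmentation and photoperiod averages over weeks.
Latitudes are restricted to |φ| ≤ 66° so civil twilight exists on every
date. All instants are converted to the site's IANA zone; durations that
must be physical (photoperiod, expected epochs of a calendar day) are
computed on the UTC timeline, while the evening length used for
photoperiod-correcting evening metrics is deliberately the *clock* duration
dusk→midnight, matching the local-time convention used throughout.
Cross-site timing comparisons (photoperiod centre, mid-sleep) are made on
the local clock, not absolute time. Mean photoperiods average over calendar
dates of the configured collection window, not over participant-days.

## Cleaning conventions

* Local calendar days run midnight→midnight in the site zone; all intervals
  are half-open [start, end). On DST transition days the true 23/25-h epoch
  count is the denominator for missingness.
* Regularisation inserts NaN epochs on the declared grid and refuses
  off-grid timestamps rather than snapping them: silent resampling would
  change threshold metrics.
* The 130 000-lx photopic ceiling excludes the whole sample (both
  channels), since a saturated sensor makes the spectral split unreliable.
* Sub-1-lx readings are kept as measured for threshold metrics and replaced
  by 0.1 lx only inside logarithmic computations, where the replacement
  exists to keep log₁₀ defined in darkness.
* A day with more than 6 h missing is invalid; exactly 6 h is still valid
  (the rule is "more than"). No non-wear detection is attempted — the
  logger records no actimetry, so charging gaps are just missingness.

## Metric battery

"Above" a threshold means ≥, "below" means ≤, uniformly. A metric whose
window contains no observed epoch is NaN, never 0. Timing metrics
(FLiT/MLiT/LLiT) are local clock hours and are averaged arithmetically
within one day — exposures are bounded inside a single local day, so
circularity only matters when correlating across days with chronotype,
where the circular correlation is used instead. PAT is the longest
contiguous at-or-above run (the alternative first-to-last-span reading
would make PAT ≥ TAT possible, which contradicts its use as a bout
length). TATd250's daytime filter follows the day segment of the same
local date. FcT counts upward crossings between adjacent observed epochs
only; pairs spanning a gap are not counted. M10m/L5m slide at epoch
resolution; a window qualifies when at least half its epochs are observed
and ties break to the earliest onset. IS and IV are computed on hourly bins
of raw (not log) mel EDI; IV differences are taken only between temporally
adjacent observed bins. Daily metrics are computed on valid days only;
participant summaries average daily metrics over valid days (per-day, then
across days — not pooled epochs).

## Questionnaires

LEBA items are 1–5 dummy-coded (never→always); factor scores are item sums
with item 4 contributing 6 − raw to F2. The shipped item→factor map
(`data/leba_factors.csv`: F1 = 1–3, F2 = 4–9, F3 = 10–14, F4 = 15–19,
F5 = 20–23) follows the instrument's published five-factor structure and is
consistent with every item–factor assignment used in the analyses; it is a
plain CSV and can be overridden if a study uses a different published
revision. PSQI components follow the standard Buysse rules; the global
score is the component sum and `poor_sleep` flags global > 5 (the stricter
of the two conventional cutoffs). The sleep schedule comes from PSQI items
1–3: onset = bedtime + latency, duration = (wake − onset) mod 24, mid-sleep
= onset + duration/2 on the 24-h circle. No workday/free-day sleep-debt
correction is applied, because the instrument does not collect day-type
information.

## Compliance

The recommendation windows are anchored to each participant's typical
schedule applied identically to every calendar day (no per-day sleep
diary): day = [wake, onset − 3 h), evening = [onset − 3 h, onset), night =
[onset, next wake). Fractions are per-day, then averaged per participant,
then per site; the overall figure time-weights day/evening/night by each
participant's own mean window durations. Missing epochs are excluded from
numerator and denominator — counting them as non-compliant would conflate
device charging with behaviour.

## Statistics

* Window averaging: an assessment's window is (previous assessment,
  assessment] within the participant; the whole-period scheme pairs the
  final assessment with the grand mean. Windowed rows are pooled across
  participants for correlation, which matches how repeated assessment
  windows enter the correlation sample; the resulting p-values treat
  within-participant rows as independent and are therefore anti-
  conservative to that extent.
* Spearman ρ is tie-corrected with p from the asymptotic t-approximation;
  BH adjustment runs over an explicit family size which may exceed the
  number of computed pairs (missing members enter as p = 1, which can only
  be conservative).
* Circular correlation is the Jammalamadaka–SenGupta statistic on angles
  2π·hours/24, with the standard asymptotic normal p-value; it is invariant
  under rotation of either variable.
* Between-site comparison uses the two-sample Fisher r-to-z test, BH
  adjusted across pairs; pairs with n ≤ 3 in either site are skipped.
* Item stability: per participant × item, assessments are resampled with
  replacement (default 10⁴); the 2.5/97.5 percentile CI of the resampled SD
  calls variation significant when it excludes 0, and an item is stable
  when at most half the participants vary significantly. Percentile CIs are
  used because the bootstrap distribution of an SD over few assessments is
  markedly skewed.
* Gap sensitivity: for each candidate gap duration, resamples draw a
  complete day at random, blank one uniformly-placed contiguous block, and
  recompute each metric; the selected threshold is the largest gap whose
  resampled means all stay within the original mean ± 2 SE band.

## Synthetic cohort

Each participant-day is a piecewise lognormal process: night level during
the sleep episode; an indoor lognormal level during waking daylight hours;
outdoor bouts whose level rises to daylight magnitude scaled by a half-sine
solar-elevation proxy (capped at 10⁵ lx); an evening level after dusk that
decays geometrically to the night level across a dim-lead window before
onset; a fixed-clock-time daily 1-h charging gap; photopic = mel EDI × a
participant ratio with multiplicative noise. Site presets encode the study
conditions: the mid-latitude preset has more outdoor time (median 80
min/day), brighter indoor days (median 150 lx), dim early evenings (median
4 lx, 1.5 h dim lead) and earlier mid-sleep (03:45 ± 0.8 h); the equatorial
preset has less outdoor time (40 min/day), dimmer days (80 lx), brighter
later evenings (18 lx, 0.3 h dim lead) and later mid-sleep (04:57 ±
1.4 h). Recordings default to 30 days at a 60-s epoch.

Questionnaire answers are ordered-categorical draws whose latent locations
are monotone in the matching behavioural parameters. The outdoor items
share a Gaussian-copula correlation with the participant's outdoor
propensity; the latent correlation is set from the target Spearman rs via
ρ = 2 sin(π·rs/6), inflated 6% to offset the attenuation from cutting one
margin into five ordinal levels (default target rs = 0.6 for the key
outdoor item against TAT1000). One global seed is split hierarchically
(numpy `SeedSequence.spawn`) per site, participant and day, so any one
participant regenerates stably and the full output is bit-reproducible.

What the generator does *not* emulate: weather and cloud dynamics,
commuting or geolocation structure, seasonal behaviour change, non-wear
other than the charging gap, sensor spectral error, or day-type (work/free)
structure. Tests passing on this cohort therefore demonstrate correctness
of the computations and recoverability of induced structure under the
stated conditions — not that real cohorts will show the same effect sizes.

## Problem sizes used in the validation suite

The recovery check runs 100 replicates of 20 participants × 30 days at a
300-s epoch (coarsened from 60 s; threshold metrics on step-like signals
are insensitive to epoch refinement) and uses the pipeline's pooled
windowed-correlation design, requiring the induced outdoor↔TAT1000 pair to
be BH-significant with positive sign in ≥80% of replicates. Site-contrast
sign checks use 8 participants per site × 14 days × 600-s epochs over 10
seeds. These sizes are the package's own validation choices; the
generator's scientific defaults remain 30-day, 60-s recordings.

## Known limitations

* The solar engine is a low-precision series; do not use it where sub-minute
  twilight accuracy matters.
* Pooled windowed correlations understate p-values in the presence of
  strong within-participant clustering (documented above, as in the source
  analyses this mirrors).
* The LEBA factor map ships as the published five-factor structure but is
  intentionally overridable; studies using a revised instrument should
  supply their own map.
* Mixed-effects and additive-model fits are out of scope: the pipeline
  prepares model-ready tables (daily and participant metrics with site and
  schedule covariates) for external statistical software.
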