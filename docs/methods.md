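# Methods

This note documents the models, conventions and design choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the numerical details a user extending the package should
know.

## Data model and time conventions

Detections are `(timestamp, receiver_id, tag_id)` triples, the export
shape of autonomous coded-transmitter receivers. Timestamps are stored
UTC; **every hour-of-day and calendar-day computation applies a fixed
local offset** (`StudyConfig.utc_offset_hours`, default +2 h, the
summer local time of the northwestern-Mediterranean study area).
Receiver logs do not carry timezone metadata, and diel quantities are
meaningless in UTC, so the offset is an explicit, configurable
assumption rather than a hidden conversion. Hour bins are half-open
`[h, h+1)`; weeks are ISO-8601 weeks of the local calendar (the weekly
correction needs an anchor and the ISO convention is the least
surprising one).

## Quality control

*Single daily detections.* A transmitter heard exactly once on a local
calendar day is treated as a false detection (code collision between
tags) and dropped. The rule is evaluated **per tag-day pooled across
receivers**, not per receiver-day: collisions corrupt the decoded tag
identity, which is a tag-level event, and a tag genuinely present
usually produces many detections per day at a 45–95 s ping interval.
The filter is idempotent and removes at most one record per tag-day.

*Presumed mortality.* Fish released in the configured high-risk window
(default 2011-05-30 – 2011-06-22, a period of strong currents that
compromised post-release recovery) are excluded when their detection
period is below 20 days **and** all detections came from the release
receiver. Release coordinates are not part of the data model, so the
release receiver is operationalized as the receiver of the fish's first
detection; for a fish that never moved (the case the rule targets) the
two coincide. Fish with zero detections are flagged `never_detected`,
not presumed dead.

## Sentinel correction

A sentinel emits `3600 / interval` pings per hour (6.67 for the 540-s
interval). The detection probability per habitat, ISO week and hour is

    p(hab, w, h) = mean over the habitat's sentinels of
                   observed(w, h) / (expected per hour × active days of w),

clipped to [0, 1]; a tag's active span is its first-to-last detection
day. Sentinels are averaged with equal weight. The corrective
coefficient is **normalized within the week**:

    c(w, h) = p̄(w) / max(p(w, h), p_floor),   p̄(w) = mean of non-missing p over hours.

The normalized form (rather than 1/p) keeps corrected counts on the raw
scale and makes "uniform detectability ⇒ no-op" an exact, testable
identity. `p_floor` (default 0.05) bounds the coefficient in dead bins;
missing cells get c = 1 with a warning. Habitats without sentinels
(seawalls, the distant coast) are left uncorrected — the correction is
only defined where a sentinel measures the environment. Corrected
counts are real-valued; area standardization divides by the configured
sampling area (1.69 km² AR, 0.75 km² NR).

## Residency metrics and classification

DP is the inclusive day span between first and last detection; DR is
the percentage of DP days with at least one detection. RI defaults to
**detection share** (per-habitat share of raw detections): the
reference per-fish table contains sub-day-resolution values (0.06 %)
that a whole-day ratio cannot produce, so detection share is what the
published quantities actually are. A `day_share` mode implementing the
verbal "days per habitat / detection days" definition is retained, with
days split across habitats contributing fractionally.

Classification: transient below DR 50 %; otherwise resident of a reef
whose RI reaches 70 %; otherwise NPH. The 70 % threshold is not printed
as a rule anywhere; it is the unique round value consistent with every
label of the reference table (minimum resident RI 71.03, maximum NPH RI
63.45) and is therefore exposed as a config parameter, documented as
inferred. Fish with DR in [50, 70) are classified by the same RI rule
(no such fish exists in the reference data; the boundary behavior is a
deliberate, documented choice).

EOPH counts maximal runs of hourly bins whose detections are all at
non-preferred receivers; undetected hours do not split a run, and a bin
containing any preferred-habitat detection terminates one. Residents
use their preferred reef as reference; transients and NPH fish use
their capture location.

Two printed aggregates of the source study are knowingly not used as
checks: the group-mean RIs quoted in its results prose and its
excursion-frequency histogram are inconsistent with its own per-fish
table; only quantities that recompute consistently from the table (the
group counts, the per-habitat visit counts, the 21 zero-excursion
residents) are asserted.

## Solar events and the diel GLMM

Sunrise/sunset use the NOAA solar-position algorithm (truncated Fourier
series for the equation of time and declination, zenith 90.833°), with
one fixed-point refinement of the event time; against an independent
high-precision ephemeris at the study coordinates the events are
accurate to well under 2 minutes. Day is `[sunrise, sunset)`.

The GLMM response is the detection count per (transmitter, local day,
hour) — the same granularity as the hourly profiles, with undetected
hours of monitored tag-days entered as zeros. Fixed effects: diel
phase (day = 1, judged at the bin midpoint), standard length in cm
(uncentered) and their interaction; size terms are omitted for
sentinels. Random intercepts for calendar day and transmitter are
**crossed**, and the marginal likelihood uses the Laplace
approximation: an inner sparse Newton solve for the joint mode of
(β, u, v) and an outer Nelder-Mead over the log standard deviations.
Fixed-effect standard errors come from the profiled Fisher information.
Correctness anchors: with variance components pinned at zero the fit
equals a plain Poisson GLM to 1e-6, and on simulated data the fixed
effects, SEs and variance components match `lme4::glmer` (the de-facto
standard Laplace implementation) to ~0.02. Corrected counts are
rounded to the nearest integer when used as a Poisson response;
raw-count fitting is the default. Non-convergence is reported
explicitly in the result object, never silently replaced.

The published coefficient tables themselves are not reproducible — the
raw detection data were never deposited — so the model is validated by
behavior: near-nominal type-I rate on null simulations, and recovery of
the sign pattern (negative day effect for nocturnal AR-residents,
positive for diurnal NR-residents) across seeded simulations.

## Wavelet periodicity

Hourly chronograms (zero-filled: absence of detections is information)
are transformed with the Morlet wavelet, ω₀ = 6, on dyadic scales with
8 voices per octave spanning 2–256 h. The transform follows the
standard geophysical convention: FFT implementation with normalization
`√(2πs/dt)`, Fourier factor 4π/(ω₀+√(2+ω₀²)) ≈ 1.033, and COI at the
e-folding time √2·s. With this normalization white noise of variance
σ² has expected power σ² at every scale, which the tests verify
empirically.

Pointwise significance compares power against σ²·P(λ)·χ²₂(0.95)/2 where
P is the theoretical AR(1) spectrum with lag-1 autocorrelation
estimated from the series (clipped to [0, 1)). This deterministic
red-noise null replaces the surrogate-resampling test of the original
analysis software: it is reproducible, standard, and its size
calibrates to 5 % ± 2 % inside the COI on null series. Cells outside
the COI are never flagged. The 24-h summary reports the fraction of
COI-admissible times with significant power within one dyadic step of
24 h.

## Synthetic generator

The generator's defaults mirror the study conditions: 74 fish in the
observed archetype proportions (20 nocturnal AR-residents, 33 diurnal
NR-residents, 6 NPH, 15 transients), a 17-receiver array (6 AR zones, 6
NR points, 2 seawalls, 3 distant-coast receivers), 3 sentinels per
reef, a 150-day window with releases staggered over the first 30 days,
uniform 45–95 s fish ping jitter, 540 ± 30 s sentinel intervals and a
151-day battery.

Occupancy is an hourly Markov chain over {AR, NR, SW, CV, away}:
residents hold their reef with self-transition 0.995 and leak briefly
to other patches or off-array; NPH fish switch between reefs (0.012/h);
transients sit off-array with self-transition 0.99 (≈ 90 % of hours
away, detection rates well below the 50 % threshold). Diel behavior is
a 24-h cosine on detectability (base 0.7, amplitude 0.25; nocturnal
peak 02:00, diurnal peak 14:00) — for a sheltering fish, activity and
acoustic visibility coincide, which is exactly the observable the
analysis interprets. The environment enters as
`d(habitat, week, hour)`: a base probability (0.65 AR, 0.60 NR) with
Gaussian dawn/dusk dips (relative depth 0.35, width 1.2 h), a 12 %
daytime boost on the NR (the pattern its sentinels showed) and seeded
lognormal weekly drift (sd 0.10) that the weekly correction is designed
to absorb. Pings are thinned Bernoulli with probability activity × d;
receivers within a habitat are drawn uniformly.

What the generator does **not** emulate: spatially explicit movement
(positions, speeds, range-dependent detection), inter-tag code
collisions (the single-daily filter is the analysis-side treatment;
synthetic data therefore contain essentially no single-daily
detections), tides/temperature as explicit covariates, and tag loss or
predation. Passing recovery tests therefore demonstrate that the
pipeline's inferences are correct *under its own assumptions*, not that
those assumptions hold for any particular field dataset.

## Problem sizes used in the tests

Unit tests run on 10-fish, 3-week studies; the classification-recovery
check runs the full 74-fish, 150-day cohort once per session (≈ 4
million detections); diel sign recovery uses 50 simulations of 4
resident fish over 12 days each; wavelet calibration uses 100 null
series of length 512. These sizes keep every Monte-Carlo criterion
comfortably powered while the whole suite completes in about two
minutes.

## Known limitations

* The release-receiver proxy (first detection) can mis-attribute a fish
  that swam to another receiver before its first detection; with
  45–95 s pings this window is minutes.
* The day-share RI mode weights days, not time, across habitats; both
  modes are detection-biased wherever detectability differs between
  habitats (the reason the sentinel correction exists for count-based
  analyses — RI itself is left uncorrected, as in the source analysis).
* The GLMM treats hours within a tag-day as conditionally independent
  given the random intercepts; serial autocorrelation at the hour scale
  is absorbed only insofar as the day intercept captures it.
* Sentinel-free habitats cannot be corrected; their counts are
  comparable only under an assumption of stable detectability.
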