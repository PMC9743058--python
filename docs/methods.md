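# Methods

This note documents the models and conventions behind `broodtrack`: what is
computed, which parameters matter, what the simulator does and does not
emulate, and where genuinely open design choices were decided.

## Data model and cleaning

A relocation is (tag id, UTC timestamp, lon/lat WGS84, satellite count). Raw
tables arrive in any delimited layout via a declared column mapping (a
Movebank-style dialect is built in); timestamps in other zones are converted
to UTC at read time. Cleaning is deliberately minimal and matches standard
practice for base-station-downloaded archival tags:

* **duplicates** — two fixes with the same timestamp after rounding to whole
  seconds (the signature of the same fix downloaded to two base stations) are
  collapsed, keeping the fix seen by more satellites, then the first
  occurrence. The operation is idempotent.
* **quality filter** — fixes from fewer than 5 satellites are dropped; no
  speed or angle filtering is done beyond this.
* **day/night** — each fix is flagged by the sun's elevation at its own
  position and date, computed with the NOAA fractional-year solar-position
  equations (accurate to ~0.2°, cross-checked in the tests against an
  independent Astronomical Almanac ephemeris). Day is elevation ≥ −6°
  (civil twilight), so crepuscular dawn and dusk count as day. The −6°
  threshold is a package decision: the boundary is conventionally named at
  dawn/dusk, and civil twilight is the standard operationalisation.

Metric coordinates come from an azimuthal-equidistant projection on the mean
sphere, centred per bird on its median lon/lat. Pairwise distance error is
below 0.1% within 50 km of the origin (property-tested), i.e. centimetres at
the 20 m analysis radius. Per-bird centring means spatially anonymised
(shifted) datasets project identically.

## Revisitation

For a focal point *c* and radius *R* (default 20 m, the tags' error scale),
a *visit* is a maximal interval during which the piecewise-linear trajectory
is inside the closed disc around *c*. Each segment's entry/exit are the
roots of a quadratic in the segment parameter — exactly linear
time-interpolation of the circle crossings. Conventions, all configurable:

* the disc is closed; a tangency creates no zero-length visit;
* every relocation is a focal point (no gridding), so a focal fix always has
  ≥ 1 visit, and "revisits = 1" means a place seen once;
* a time gap longer than 4× the nominal sampling interval breaks a visit and
  accrues no residence, because the bird's position across an outage is
  unknown. Without this rule a dead tag at a roost would fabricate days of
  residence.

Weekly profiles (histograms of per-fix visit counts) are computed on the
windowed sub-trajectory, so each week is self-contained and cross-window
movement cannot leak in. The engine is validated against a 1-s
dense-resampling brute-force oracle: identical visit counts and crossing
times within 2 s (sub-second grazing passes that fall between the oracle's
samples are analytically real but unresolvable at the oracle's step, and
are excluded from the comparison on that ground).

## Nest localisation

Within an incubation window: revisitation stats → the ⌈20%⌉ most-revisited
fixes (ties broken by residence, then time) → K-means (k-means++, 50
restarts, fixed seed) with k = 3 → the highest-support centroid. On
simulated incubation with 10 m GPS noise the median error is ~12 m. The
error is dominated by a small outward bias, not noise averaging: fixes a few
metres off the nest centre accumulate slightly *more* disc entries than the
centre itself (on-bout jitter churns across their boundary), so the
top-revisited set forms a thin annulus and the winning cluster is one sector
of it. This is a property of count-ranked selection generally, is well
inside the tags' own error radius, and is why the acceptance bar is stated
as a multiple (1.5×) of the noise SD.

## Stage classification

Five features per window, all invariant to rigid motion of the coordinates:

| feature | meaning |
|---|---|
| `prop_single` | fraction of fixes with exactly 1 visit |
| `dominant_focus_share` | largest fraction of window fixes within R of any one fix |
| `mid_mass` | fraction with 2–10 visits |
| `max_visits_norm` | max visit count ÷ window fix count |
| `drift_rate` | mean consecutive daily-centroid displacement, m/day |

The cascade (defaults in `ClassifierConfig`):

1. **incubation** if `dominant_focus_share ≥ 0.30` and
   `max_visits_norm ≥ 0.15` — a strong focus revisited very often;
2. else **chick guarding** if `mid_mass ≥ 0.40`,
   `dominant_focus_share < 0.30` and `drift_rate ≤ 500 m/day` — mid-range
   revisits around a slowly moving centre;
3. else **non-breeding**, split into pre-/post-breeding purely by position
   relative to the bird's incubation segments, since the two profiles are
   equivalent.

These thresholds quantify qualitative, visual criteria; they were calibrated
once on the simulator's stage-labelled windows and are exposed in config
rather than hard-coded. Windows need ≥ 10 fixes; weeks are ISO calendar
weeks; all windows are half-open `[start, end)` in UTC.

### Timeline segmentation

1. **Coarse pass**: classify each calendar week; data-thin weeks inherit the
   nearest classified label; collapse into runs.
2. **Interior scan**: a failed-and-renested attempt can hide entirely inside
   one coarse run (a 5-day gap never dominates a week). Rolling 3-day
   windows (step 1 day) across each long run recover interior blocks of ≥ 2
   consecutive windows of a different label, at day resolution.
3. **Day refinement** at each run boundary: the first day whose 3-day window
   (and the next, to ride out a single misclassified window) carries the new
   label.
4. **Hour refinement**: for boundaries into/out of incubation, nest
   occupancy (fraction of fixes within R of the nest) per 6-h block; the
   transition is the first block from which occupancy stays on the new side
   of 0.2. Leaving incubation, the kind is resolved behaviourally: HATCH if
   the daily activity centre then drifts ≤ 500 m/day and stays within 2 km
   of the nest for 48 h (mobile brood), otherwise nest failure. Leaving
   chick guarding, the first > 2 km inter-fix displacement inside a wide
   bracket dates the brood loss. Empty occupancy blocks (duty-cycled data)
   carry no evidence and neither trigger nor veto a transition.
5. Segments tile the tracked span (minimum length 1 day); segments whose
   length is implausible for the stage (> 1.5× the expected ~28 d incubation
   or ~35 d chick rearing) are annotated, never overwritten.

Birds with no incubation segment anywhere are non-breeders; their whole
track is one undifferentiated non-breeding segment.

On 100 simulated birds at 15-min sampling this recovers 100% of
truth-homogeneous week labels and times transitions with ~1–2 h median
error (6-h blocks set the resolution); the half-day accuracy bar is met
with a wide margin. Agreement is measured on weeks lying wholly inside one
truth segment — a transition week has no single true label to agree with.

## Outcomes and nest survival

Each maximal incubation segment is an attempt; fate = HATCHED if chick
guarding follows, FAILED if non-breeding movement follows, CENSORED if the
record ends mid-incubation. Population percentages are integer-rounded
(half-up), matching the precision such tables are reported at.

Daily nest survival uses the exposure-day estimator: DSR = 1 − f/E
(maximum likelihood under constant daily survival), CI by profile
likelihood on `p^(E−f) (1−p)^f`. Exposure is the full observed incubation
interval with **no midpoint correction** by default: the classic half-day
midpoint adjustment compensates for failure dates known only to the day,
and the occupancy refinement already dates failures to ~6 h. A `midpoint`
mode is provided for comparability with day-resolution studies. Calibration
(simulated cohorts of 200 nests, geometric failure days, 28-day cap, 500
replicates at true DSR 0.90/0.95/0.99): |bias| < 0.001, CI coverage
0.94–0.96.

The packaged study-cohort fixture (23 birds, 25 attempts) gives
DSR = 1 − 16/294 ≈ 0.9456. The printed per-attempt intervals are the only
exposure ledger recoverable from the published tables, and their sum need
not equal the exposure ledger behind the originally reported estimate
(0.935); no equality is asserted between the two, and the estimator is
validated by closed-form identity and simulation instead.

## Sampling-scheme sensitivity

`thin` reduces a 15-min track to a coarser grid (nearest fix per grid slot,
grid anchored at the first fix and bounded by the span — a deterministic
choice; decimation vs aggregation is not otherwise specified by the
problem) or to morning-only fixes (08:00–13:59 UTC inclusive, i.e.
`[08:00, 14:00)`). `min_window_eval` tiles the span with L-day windows and
returns the smallest L at which thinned-window labels agree with truth on
≥ 90% of truth-homogeneous windows.

Finding: on these simulations the feature cascade stays reliable down to
the coarsest tested schedule (minimum window 3 days throughout), so the
asserted property is the ordering — the minimum window never *shrinks* as
sampling coarsens. An analyst reading histograms by eye degrades faster
than the cascade because the features are proportions that remain estimable
from fewer fixes, while a visual bimodality judgement needs well-populated
histograms; the strictly increasing day-requirements reported from visual
analysis are therefore not expected to reproduce here, and are not asserted.

## The simulator

`simulate` generates the study conditions: 15-min fixes, 24 h/day, over
weeks; 10 m GPS noise (the tags' ~10–20 m error scale); a 23-bird cohort
with 26% non-breeders and renesting in ~30% of breeders; geometric failure
days under daily survival 0.95 capped at 28 days; failure followed by a
multi-km displacement and wide-ranging movement. Movement regimes:

* **non-breeding**: correlated random walk — gamma(2) step lengths (mean
  200 m per 15 min), wrapped-Cauchy turns (ρ = 0.7) — with a weak pull
  (2%/fix) toward a home centre, keeping ranges at the few-km scale the
  study birds used (mean maximum displacement ~9.6 km).
* **incubation**: alternating on-nest bouts (nest + 3 m settling jitter)
  and foraging excursions within 800 m; exponential bout lengths, means
  45 min on / 20 min off (duty ≈ 0.7). The bout-scale values are
  placeholders — true curlew duty cycles are not parameterised here — chosen
  so that weekly profiles reproduce the qualitative published shapes
  (strongly bimodal incubation weeks). Only the tagged bird is simulated;
  its mate's share of incubation is outside the model.
* **chick guarding**: a latent brood point drifting near-ballistically
  (300 m/day, heading SD 0.05/fix) with the adult dispersed 100 m SD around
  it. Ballistic drift matters: a meandering brood re-crosses its own path
  and pushes per-fix visit counts above the "few visits" band that defines
  the stage's profile.

What the simulator does **not** emulate — and hence what passing tests do
not show about field data: habitat structure and barriers, tag outages and
irregular fix success, behavioural idiosyncrasy between individuals (every
simulated bird shares one parameter set), shared incubation by the mate,
partial clutch loss, weather-driven movement, and observer-grade label
noise (truth is exact). Field performance of the thresholds should be
expected to be worse than the simulation numbers; the simulation
establishes that the pipeline is internally consistent and that the
published qualitative signatures are sufficient statistics for stage
recovery under the stated conditions.

## Numerical choices and degenerate inputs

* K-means: scikit-learn, k-means++, 50 restarts, caller-supplied seed;
  k reduced to the point count when larger; deterministic tie-breaks
  throughout (ranking by visits, then residence, then time).
* Revisits: focal points processed in chunks of 512 to bound the
  segment×focal matrices; degenerate zero-length segments fall back to a
  point-in-disc test; a single-fix trajectory yields one zero-length visit.
* Profile CI: Brent root-finding on the log-likelihood-ratio; f = 0 gives
  an upper bound of exactly 1.
* Empty windows, empty files and single-point trajectories return empty
  results rather than erroring; genuinely unusable inputs (< 3 days of
  track, < 10 fixes in a window) raise `InsufficientDataError`.
* Problem sizes in the shipped benchmarks (100 birds for stage inference
  with ~40-day lives, 50 incubations for nest error, 500 replicate cohorts
  for survival calibration, 3 birds for the sampling grid) were chosen as
  the package's own benchmark conditions; all are parameters of the
  `evaluation` functions.

## Known limitations

* The classifier thresholds are simulator-calibrated defaults, not field
  estimates; new species or tag error scales will need the config re-tuned.
* Nest localisation inherits a small outward bias from count-ranked
  selection (see above) — negligible at tag-error scale but real.
* Chick-guarding detection rests on the mobile-brood signature; a brood
  that parks in one field for days would resemble a weak incubation focus.
* PRE vs POST disambiguation is purely positional; a bird tagged after a
  failure elsewhere would be called pre-breeding until its next attempt.
* The survival model is constant-DSR with no covariates, matching the
  single-rate reporting convention for small cohorts.
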