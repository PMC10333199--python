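# Methods

## The analysis problem

Automated VHF telemetry networks log detections of coded tags at fixed
receiving stations. The data are sparse in two ways that shape every method
here: a bird is only seen when it passes within range (~15 km) of a station,
and receiver noise sometimes decodes as a valid tag id. The pipeline turns a
raw detection table into: cleaned detections and station bouts, per-bird
departure estimates, a Delaware Bay use classification, stopover events, and
flight ground speeds with tailwind support.

All timestamps are UTC end to end (ISO-8601 in files, timezone-aware
`datetime64` in memory); no local-time arithmetic occurs anywhere.
Coordinates are WGS84 decimal degrees with longitudes in [−180, 180).
Distances are great-circle (haversine) on a sphere of radius 6371.0 km; at
the 30–150 km thresholds used by the rules, the ≤ 0.5 % departure from an
ellipsoid is immaterial, and a spherical model keeps every geometric test
closed-form (bearings, interpolation along tracks, cross-track distance to
region boundaries, all on the same sphere).

## Detection QC

Rules are applied in a fixed order with first-match attribution, so the QC
report's counts are well defined and conserve the input
(`n_input = n_valid + Σ rejected`):

1. **R1, pulse count** — a genuine burst has 3 consecutive pulses; fewer is
   rejected (`min_pulses = 3`).
2. **R2, burst-interval consistency** — within each tag-at-station sequence,
   the gap between successive detections must be within `±0.1 s` of k times
   the tag's burst interval, k = 1..10 (`k_max` bounds the number of missed
   bursts searched, keeping the rule decidable). Consecutive consistent
   detections form a run; runs shorter than `min_run_bursts = 3` are
   rejected, since one or two aperiodic hits cannot be distinguished from
   noise. This is the whole operationalization of "noise context": no
   station-level noise model is attempted because none is identifiable from
   burst-level data.
3. **R3, frequency offset** — |offset| > `freq_tol_khz` (default 4 kHz) when
   the field is recorded.

Filtering is idempotent: survivors are, by construction, in consistent runs
of ≥ 3, so a second pass rejects nothing. Bouts then group each tag's
time-sorted detections, splitting on station change or a same-station gap
above `bout_max_gap_min = 30` min; the threshold is a convention (receivers
duty-cycle and birds drift in and out of range), so it is configurable.

## Departure timing

`stopover_min_dist_from_capture_km = 50` defines "away from the capture
site", reused from the stopover rule for consistency. A first away bout
inside the inland-Carolinas region gives a known date — an inland detection
means migration has begun, whereas a coastal one may be local movement.
Otherwise the bird receives an inclusive uniform window from deployment date
to first-away date: both endpoints are candidate departure days, which is
what makes a deploy-day-to-day+4 window a 5-day window with weight 0.2/day.
Windows are exact by construction (weights renormalized to sum to 1 within
1e−9). The timeline is the superposition of per-bird weights; its total mass
equals the number of contributing birds. The weighted median is the smallest
date at which cumulative normalized mass reaches 0.5. Birds never detected
away from the capture site yield no estimate and are reported as excluded
rather than silently dropped. Resolution is one calendar day; no time-of-day
estimation is attempted.

## Route classification

Stations within `bay_buffer_km = 30` of the Delaware Bay watershed polygon
count as "in the bay" (distance to a polygon is 0 inside, else the minimum
spherical cross-track distance to its boundary arcs). The tree is evaluated
in order and is total — every bird with an in-season post-deployment bout
gets exactly one class:

1. **stopped** — ≥ 2 bay bouts spanning > `min_stop_days = 1` day.
2. **likely_stopped** — ≥ 2 bouts in the annulus 30–90 km from the bay
   (`likely_buffer_km = 60` beyond the buffer) on ≥ 2 calendar days. The 60
   km width quantifies "just outside the bay"; it is a judgment call and
   configurable.
3. **skipped** — detected north of the bay's maximum latitude with slack
   time below one day, where slack = (first detection above bay latitude −
   last detection at/below it) − great-circle distance / 20 m s⁻¹. The
   assumed transit speed is the typical observed net ground speed of
   migrating knots; with it, "no time for a bay stopover" becomes decidable.
   Any bay detections must look like a fly-through (all within one day).
4. **likely_skipped** — same northern evidence with slack ≥ 1 day but every
   intermediate detection inland: inside the Great Lakes Basin or more than
   `inland_offset_km = 150` km west of the Atlantic coastline polyline.
5. **unknown** — anything else (including birds whose first detection is
   already north of the bay, where no slack can be computed).

Headline proportions pool `stopped + likely_stopped` and
`skipped + likely_skipped` over classifiable (non-unknown) birds. The
mass-vs-strategy comparison is a classical one-way fixed-effects ANOVA from
between/within sums of squares (F, p from the F distribution, R² = SSB/SST),
on the three pooled groups.

## Stopovers

Only bouts at stations > 50 km from the tagging location are considered.
Two rules generate candidate windows over a bird's bout sequence: a maximal
same-station run spanning **strictly more than 4 h**, or a maximal run whose
stations form a ≤ 30 km **clique** (max pairwise distance, the strictest
reading of "within 30 km of each other") spanning strictly more than 6 h
with ≥ 2 distinct stations. Overlapping qualifying windows merge into one
stopover, so each bout belongs to at most one event; for small inputs the
result provably equals exhaustive enumeration of maximal qualifying runs
(tested against a brute-force oracle). Ties at exactly 4.0/6.0 h are *not*
stopovers. Durations are closed intervals (last − first detection). The
finer distinction between multiday refueling stops and brief rests is
deliberately not encoded.

Delaware Bay presence duration is (last − first bay detection)/86 400 s per
bird with ≥ 2 bay detections — note this includes fly-through birds with
near-zero durations, not only classified stoppers.

The heat map is a raster: each cell counts the distinct individuals with a
stopover station within 50 km of the cell center (an individual counts once
per cell regardless of how many stopovers it had). This gives identical
counts to overlaying buffered polygons at cell resolution (default 0.25°)
while avoiding geodesic polygon buffering.

## Flights and wind support

Consecutive same-station bouts collapse into station visits. Every visit
pair ≥ 150 km apart with positive elapsed time ≤ 18 h (inclusive — "18 h or
less") is a candidate flight; departure is the last detection at the first
station and arrival the first detection at the last, so net ground speed =
displacement / elapsed slightly *underestimates* for a bird lingering in
range and slightly *overestimates* for a bird detected only at range edges.
Total length chains great-circle legs over all stations passed and always
≥ displacement (triangle inequality, equality iff collinear). When candidate
flights share a station, the largest displacement wins, ties to the earlier
departure — a deterministic rendering of "one bird may contribute several
flights provided their trajectories share no receiver".

Wind is sampled at the departure station's coordinates (the time rule is
fixed by the data product — nearest 6-hourly slice, ties to the earlier
one — but the location is a choice; sampling at the route midpoint is
available). Spatial interpolation is bilinear by default with a
nearest-node mode. Tailwind is the signed projection u·sin β + v·cos β with
u eastward and v northward (reanalysis convention: the vector points where
air moves to); |tailwind| ≤ wind speed with equality iff aligned, and the
sign flips under β → β + 180°. The speed–tailwind association is a Pearson
correlation from centered cross-moments with a two-sided p from the
t-transform on n − 2 df.

## Synthetic data generator

The generator exists to test the pipeline, not to model knots. It emulates:

- **Network**: 15 stations (inland SC, coastal corridor, a 3-station
  Delaware Bay cluster, a Great Lakes corridor, James/Hudson Bay) with no
  station within 150 km of the capture site, mirroring the coverage gap that
  forces departure windows. `coverage="dense"` adds mid-leg stations;
  `"sparse"` removes five, which measurably raises the unknown-strategy
  fraction.
- **Birds**: three route strategies — bay stopover (2–17 d, longer for
  earlier arrivals), inland skip through the Lakes, and Atlantic non-bay
  stopovers (Chesapeake / New York Bay). Defaults are 12 / 20 / 8 = 40
  birds, deployments spread over two weeks from late April, morning (06–10
  UT) departures 1–5 days after tagging. Tracks are piecewise great-circle
  segments with constant per-leg speed = airspeed (16 ± 1 m/s) + 1.0 ×
  tailwind at the leg start + N(0, 2 m/s), floored at 6 m/s — matching the
  pipeline's own kinematic assumptions so truth is computable in closed
  form.
- **Detections**: bursts lie exactly on each tag's burst-interval lattice
  (4.7–11.3 s, as real nanotags) and are kept with `p_detect = 0.8` while
  the true position is within 15 km of a station; stationary birds are
  duty-cycled into hourly clusters of 6 bursts to keep volumes realistic.
  False positives arrive as a Poisson process (1 per station-day) with
  uniform times (hence aperiodic gaps), 1–3 pulses and broad frequency
  offsets — so all three QC rules are exercised.
- **Wind**: a 6-hourly 2.5° grid over 25–60° N, 95–60° W; mean southwesterly
  flow (u = 2, v = 3 m/s) plus traveling-wave perturbations rescaled to a
  4 m/s pointwise standard deviation and clipped at 25 m/s — giving the
  day-to-day tailwind variability (and ~80 % tailwind departures for
  northbound flights) that real synoptic systems produce.
- **Determinism**: one global seed; each bird draws from its own substream
  keyed by (seed, bird index), so adding a bird never changes another's
  track. Same seed ⇒ byte-identical outputs.

What the generator does *not* emulate — and therefore what passing tests do
not establish about field data: behaviorally realistic movement (no
correlated random walks or state switching), within-flight wind drift or
altitude, station-specific antenna patterns and noise regimes, tag loss and
mortality, or real watershed geometries (regions are idealized rectangles
and a simplified coastline, labeled synthetic). Recovery rates near 100 %
on synthetic cohorts demonstrate internal consistency of the rules, not
expected field performance.

## Numerical conventions and degenerate inputs

- Strict vs inclusive boundaries: stopover spans strict (> 4 h, > 6 h), bay
  stop strict (> 1 d), flight filters inclusive (≥ 150 km, ≤ 18 h), window
  endpoints inclusive.
- Weighted median: smallest date with cumulative normalized mass ≥ 0.5.
- Bearing of coincident points, ANOVA with all-constant data, Pearson or OLS
  with zero variance, empty heat-map grids, and out-of-domain wind queries
  all raise informative errors rather than returning NaN.
- Rows failing type coercion on load raise schema errors naming the column;
  cross-table violations (detections at unknown stations/tags) raise
  referential-integrity errors. Station activity periods are validated but
  not filtered on by default, since activity-period handling is not part of
  the rule set.
- Report p-values are plain (no multiple-testing correction is applied
  anywhere, by design); every number in the report is recomputable from the
  per-stage tables written next to it.

## Problem sizes

Default test and demonstration cohorts use 40 birds (~50 k detections,
~230 six-hourly wind slices on a 15 × 15 grid), which exercises every rule
and yields ~40 migratory flights — comparable to the scale such a field
study produces — while a full test run stays under a minute. Statistical
calibration checks use 200 correlation replicates and 10 000 null ANOVA
simulations.

## Known limitations

- The slack-time skip test assumes a fixed 20 m/s transit speed; very slow
  (strong headwind) transits inflate slack and can push a true skipper to
  `likely_skipped` or `unknown` — conservative, never toward `stopped`.
- Flight segmentation ("maximal station passages, largest displacement
  wins") is one decidable convention among several the verbal definition
  admits; alternatives would change which of several overlapping candidate
  flights is reported, not the kinematics of any reported flight.
- Multi-station stopover clustering is pairwise (clique); a chain reading
  would merge more stations at the margin.
- Wind is sampled at a single point and time per flight; no along-route
  averaging or pressure-level selection beyond the given grid.
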