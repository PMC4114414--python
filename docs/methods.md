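# Methods

## The analysis model

The pipeline treats a participant's GPS record as a time series of
fixes and derives everything from two primitives: the haversine
great-circle distance (sphere of radius 6371.0088 km, the IUGG mean —
the sub-0.5% error of a sphere against the ellipsoid is irrelevant at
the 500 m decision scale) and the inferred home location.

**Home inference.** "Home" is the statistical mode of the recorded
coordinates. A mode of continuous coordinates is undefined without
discretization, so fixes are binned on a fixed latitude/longitude grid
of pitch `cell_size_deg` (default 1e-4°, ~11 m — matched to typical
~10 m outdoor smartphone GPS accuracy so a stationary dwell's noise
cloud concentrates its mass in a few cells). The cell with the most
fixes wins; ties break to the lexicographically smallest
`(lat_index, lon_index)` pair, a fixed arbitrary rule that makes the
estimate order-invariant and reproducible. The reported home is the
point mean of the fixes in the modal cell, which removes the half-cell
quantization bias. Caveat: the estimator assumes the participant
records more dwell time at home than anywhere else; a participant who
records only while out would get their workplace as "home". The cell
pitch is configurable; results are insensitive to it over 1e-5°–1e-3°.

**At-home rule and trip detection.** A fix is at home when its
haversine distance to home is ≤ `radius_km` (default 0.5 km; the
boundary counts as home — the tie is measure-zero and a convention
must be fixed). The trip detector is a two-state machine (at home /
not at home) stepped over fixes in time order; because there is no
hysteresis, its trips are exactly the maximal runs of the not-at-home
mask, which is how the production code computes them (vectorized).
The test suite keeps an independent per-fix state-scan oracle and
asserts exact equivalence on random traces. Conventions fixed here:

- departure = first fix observed *outside* the radius; return = first
  fix back *inside* (timestamps of the transitions the machine sees);
- a trace that starts away from home opens in the not-at-home state
  with the first fix as departure; such open-start trips, and open-end
  trips when the trace ends away, are flagged and excluded from counts
  unless `count_open_trips` is set — the data never shows the missing
  endpoint, so inventing one would bias durations;
- excursions shorter than `min_trip_duration` (default 15 min) are
  retained with `qualifying=False` rather than deleted, so time
  accounting and audits stay consistent; counts use qualifying trips;
- recording gaps inside a trip are passed through untouched: the
  machine sees only fixes.

**Metrics.** Time is accounted in inter-fix intervals within a
recording session (a session break is any gap > `session_gap`, default
5 min — the protocol samples at ~1–10 s, so any materially larger gap
means the logger was off; a boundary-equal gap does not split). Each
interval's duration is attributed to the at-home status of its
*earlier* fix (left-constant interpolation — the natural convention
for a high-rate stream) and to the local calendar date of its start,
with midnight-spanning intervals split proportionally by time.
Percentage of time at home is a percentage of *recorded* time: gaps
between sessions enter neither numerator nor denominator. Trips per
week is `qualifying_count * 7 / recorded_days`, where recorded days
count distinct local dates with at least one fix. Metrics that are
undefined (empty trace, zero recorded time) are explicit nulls, never
zeros, so group summaries can exclude them.

**Daily distance.** Two readings of "mean daily distance" are
implemented and stamped into every output: `max_home_distance` (the
day's furthest fix from home; the default) and `path_length` (summed
consecutive-fix haversine). The default is the home-distance reading
because the path integral of a noisy high-rate stream is dominated by
jitter — at σ = 10 m and 10 s sampling a stationary day accrues
~30 km of spurious length (two i.i.d. 2-D errors per segment give a
mean step of ~σ√π ≈ 18 m, ~8 640 segments/day) — and because the
home-distance series is the quantity the rest of the analysis is built
on. `path_length` remains available for low-noise or smoothed data.

**Group statistics.** Small cohorts (9 vs 7 in the motivating study)
rule out parametric assumptions: groups are summarized by median and
IQR (linear-interpolation quantiles) and compared with the
Mann-Whitney U test using midranks, tie-corrected variance, no
continuity correction, U oriented as wins of group 1, two-sided p from
the normal approximation. These conventions are stamped in every
result object. No multiple-testing correction is applied across the
four metrics (the comparison is descriptive for cohorts this small);
that too is recorded in the output metadata. The normal approximation
is known to be coarse below roughly n = 8 per group — the test suite
documents its deviation from the exact permutation p (computed by full
enumeration) and checks its type-I calibration under a null simulation
(3–7% rejections at α = 0.05 over 2000 replicates). PD participants
are severity-ordered by the *sum* of the motor (0–39) and nonmotor
(0–12) baseline partial-UPDRS subscales, ascending, ties broken by
participant id; per-subscale ordering is available, and participants
missing a score are flagged and sorted last, never dropped.

**Privacy.** Every reporting surface (scatter data, heat grids, JSON
bundles, CLI outputs) emits mean-subtracted coordinates — the trace
centroid is removed, preserving the shape of movements while revealing
no absolute location. Heat grids hold dwell *seconds* per cell (same
interval attribution as the metrics), not fix counts, so irregular
sampling does not distort the map; grid mass therefore equals recorded
in-period time exactly, a conservation law the tests assert. The
default grid is 100×100 bins over the mean-subtracted bounding box
padded 5%.

## The synthetic-data generator

The generator emulates the recording protocol the analysis assumes:
one 4–6 h recording window per day (a phone battery charge cycle) at a
uniformly drawn start hour (08:00–14:00), over `n_days` days with a
10% chance a day records nothing; a fixed home; out-and-back community
trips; fixes every `sample_interval_s` (default 10 s — the study
protocol's 1 s stream is available via `sample_interval_s=1` but 10 s
keeps test cohorts fast at identical analysis behavior, since every
decision rule works on distances and timestamps, not sampling rate);
and isotropic Gaussian noise of σ = 10 m converted to degrees in the
local tangent plane at the home latitude (adequate at city scale).

Trips per day are Poisson with group-level means taken from the
motivating study's scale — 6.07/7 ≈ 0.87 per day for the PD-like
group over 40 recorded days, 3.97/7 ≈ 0.57 over 22 days for controls.
Destination distance is log-normal (median 4 km, log-σ 0.6) with a
floor of 0.75 km: under a 500 m home radius, nearer errands are
indistinguishable from home, so the generator only plants trips the
detector could in principle see. Travel is straight-line at a uniform
20–50 km/h, destination dwell uniform 20–90 min, and trips are
separated from each other and from window edges by ≥ 20 min of home
dwell; trips that cannot fit the window are re-sampled a bounded
number of times, then dropped with a note in the truth log. Cohort
simulation derives child seeds deterministically from one master seed,
scatters homes so participants do not share a location, and plants a
severity signal in the PD group: trip-rate multipliers fan out
geometrically (×0.5–×1.6) while baseline UPDRS scores decrease
strictly with the rate, so severity-ordered analyses have a known
monotone trend to recover. Identical config and seed reproduce the
trace byte-for-byte.

What the generator deliberately does not model: road networks and
realistic paths (the analysis only consumes distances from home and
timestamps), indoor GPS degradation, multi-home living, mid-trip
recording dropouts, and the behavioral bias of participants switching
the phone on preferentially when going out. That last point matters
for interpretation: real cohorts recorded a *lower* share of time at
home than the generator's dwell-dominated days produce, so passing
recovery tests demonstrate the pipeline recovers what the generator
planted, not that synthetic metric levels match any real cohort's.

## Problem sizes and numerics

The validation suite runs the full recovery check at the study's shape
— 16 participants (9 + 7), 40 recorded days each, 10 s sampling,
~1.1 M fixes — and asserts home recovery within 50 m, exact
qualifying-trip counts, and % time at home within 2 points of truth
for every participant. Distance computations clip the haversine
argument into [0, 1] before the arcsin to guard rounding at antipodal
and coincident points. CSV round-trips fix timestamps at 1 s and
coordinates at 6 decimal places (~0.1 m); metric CSVs are written with
fixed formatting so identical inputs give byte-identical outputs.

## Known limitations

- Home inference fails for participants whose recorded dwell is mostly
  away from home; no multi-residence or home-drift handling.
- The 500 m radius makes sub-500 m mobility invisible by design.
- The FSM has no hysteresis band; fixes jittering across the radius
  create short non-qualifying blips (this is what the 15 min filter
  absorbs) and can shave a minute off a trip's nominal duration.
- Asymptotic Mann-Whitney p-values are coarse for groups smaller than
  ~8; the exact-enumeration helper is provided for such cases.
- Calendar days use one configured timezone per study (default UTC);
  multi-timezone cohorts need per-participant runs.
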