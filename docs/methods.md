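# Methods

## The problem

Passive acoustic telemetry receivers log every decoded transmitter ping.
Four well-known contamination processes affect the raw record: overlapping
downloads duplicate rows byte-for-byte; receivers keep logging while on
deck or in transit between deployments; transmitters from outside the study
(or test tags) appear in the array; and code collisions or noise produce
*ghost detections* — decoded IDs with no tag present. Ghosts come in two
observable flavours: isolated single pings, and pings that would require
the animal to have crossed implausible distances in the available time.
`pingfilter` removes each class with an explicit rule, keeps every removed
row in a named bin, and enforces row conservation (`input = kept +
Σ bins`) at every stage.

## Stage semantics and numerical choices

**Compilation.** Files are processed in lexicographic name order, so the
"first occurrence" that survives duplicate partitioning is deterministic.
The duplicate key is (transmitter, receiver, timestamp) only — extra sensor
columns are deliberately ignored, since collision-free sensor bytes on an
otherwise identical row still describe one physical ping; fractional
seconds, when present, do participate in the key. Batching
(`batch_size`) bounds memory while compiling and provably cannot change the
result (tested by exact table equality at batch sizes 1, 3 and all).
Timestamps are normalized to UTC at ingest; a per-input constant clock
offset may be declared. Datetime formats may be strptime patterns or
order strings (`ymd HMS`), the latter tolerating any non-alphanumeric
separators.

**Attribution.** Deployment windows are closed intervals `[start, end]`:
retrieval times are usually written down after the unit stops listening, so
a boundary detection is trusted. Overlapping windows for one receiver are a
hard validation error — attributing arbitrarily would be silent data
corruption. Tag reuse resolves each detection to the animal with the latest
`tagged_at ≤ t`; a detection exactly at a retagging instant belongs to the
new animal. `discard_first` (hours, default 0) drops the immediate
post-surgery period per tagging event; discarded rows are binned with the
unknown tags, mirroring how field crews treat them. After validation the
three metadata tables are re-written in a canonical layout so subsequent
runs need no column re-mapping.

**Solitary rule.** Grouping is always per animal; `per_receiver`
(default true) additionally scopes the neighbourhood to one receiver. A
detection is solitary iff its gap to the previous and to the next group
member are both `≥ delay` (missing neighbour = infinite gap). Ties at
exactly `delay` are solitary; identical timestamps have gap 0 and rescue
each other. Flags are computed simultaneously and removed in one pass.
One pass is also sufficient: a solitary row has no neighbour within the
delay, and the neighbour relation is symmetric, so removing flagged rows
can never isolate a kept row — the kept set is a fixed point (asserted in
the tests). Two monotonicities hold and are property-tested: array-wide
grouping never flags more than per-receiver grouping, and the solitary set
shrinks as `delay` grows (a wider window is easier to be rescued in).

**Speed rule.** Station-to-station distances come from the haversine
formula on a sphere of radius 6 371 000 m, or from a supplied in-water
matrix (validated: matching labels, symmetry to 1e-6 relative tolerance,
zero diagonal) for study areas with landmasses. Both endpoint detection
ranges are subtracted from the distance before dividing by Δt — the
animal only has to cross the water between the two detection footprints;
this double-ended subtraction is the conservative bound and can be switched
to single-ended (`both_ends=False`). Ranges are a scalar or a
time-varying table keyed by the spatial table's range category. The speed
model `v = base · x^exponent` is declared with an explicit unit: `m/s`
(converted ×3600) is the natural unit for body-length scaling laws — the
critical-speed example `0.019 · 616^0.75` m/s ≈ 8457 m/h — while a flat
`base` with no factor is taken as m/h directly.

Filtering sweeps each animal's detections in (timestamp, receiver) order —
the lexicographic tie-break makes simultaneous detections deterministic —
vetting each detection against the **last retained** one: a failing
detection (required speed above the animal's maximum, or raw station
distance above `max_distance` when set) is flagged and skipped as an
anchor, so a single teleport ghost does not condemn the genuine detection
that follows it; the *later* member of an infeasible pair is always the one
removed, since the earlier one was already vetted against its own
predecessor. Sweeps repeat until one flags nothing. Each non-final sweep
strictly shrinks the retained set, so the pass count is bounded by n; a
Δt = 0 pair across a positive effective distance implies infinite required
speed and is always infeasible. An independent audit routine re-scans kept
output for consecutive-pair violations and is asserted to find zero on
every test fixture.

## The synthetic-study generator

`FixtureConfig` defaults define the reference study: 4 animals, 3 stations
1500 m apart on an east–west line at 54° N, 14 days with a 24 h mid-study
service break (all receivers lifted), an average 1.5 detections per
animal-hour emitted in residency bouts every 3 h, receiver range 150 m,
solitary delay 1 h, and the critical-speed model `0.019 · TL^0.75` m/s on
total lengths drawn uniformly from 450–750 mm (maximum speeds ≈ 6100–10300
m/h). Ten rows per contamination class are planted.

Construction guarantees separability — each planted row violates exactly
one rule:

- genuine bouts hold ≥ 3 detections 30–150 s apart at one station, and
  animals move at most one station (1500 m) between consecutive bouts hours
  apart (≈ 500 m/h required, far below any animal's maximum), so genuine
  data survives both filters;
- *solitary ghosts* occupy emptied bout slots, ≥ 2× the delay from every
  other same-animal detection;
- *teleport ghosts* sit at a non-adjacent-in-time station seconds after a
  bout (required speed ≳ 140 000 m/h) and are planted in same-receiver
  clusters of two or three so the solitary rule cannot claim them — a
  single ghost row is rejected as an infeasible configuration;
- *out-of-window* rows use known tags during the service break, ≥ 1 h from
  the closed window boundaries;
- *unknown tags* draw from a disjoint transmitter namespace inside valid
  windows; *duplicates* are exact copies of genuine rows.

All times are generated at whole-second resolution and every draw comes
from one seeded generator, so a fixed seed yields byte-identical files.

What the generator does **not** emulate: acoustic propagation and collision
physics, detection-probability decay with range, receiver clock drift,
ecological movement behaviour (the walk is a kinematic Markov chain), or
ghosts that violate several rules at once. Passing the recovery tests
therefore shows the rules are implemented exactly as specified, not that
these rules are sufficient for any particular real array.

## Problem sizes

The reference study compiles to ≈ 2000 rows; oracle-equivalence checks run
200 random instances up to n = 500 against an O(n²) neighbour scan, and
row-conservation checks run 50 randomized 4–6-day studies. These sizes
exercise every code path (including the iterative speed sweep's
convergence) while keeping the default suite fast; all scale linearly via
`FixtureConfig` for larger experiments.

## Known limitations

- The speed filter's forward sweep never removes an animal's first
  detection; a ghost that happens to be first in an animal's record
  survives the speed rule (it is usually caught by the solitary rule).
- In-water least-cost distances are accepted but not computed; haversine
  distances ignore landmasses.
- The actel export freezes that package's documented column headers; it is
  an external contract and may need updating if the downstream validator
  changes.
- Exported timestamps are serialized at second resolution; sub-second
  detections survive the pipeline itself but not the actel export
  round-trip.
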