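# Methods

`socialvec` analyzes how hippocampal populations represent the position of a
conspecific during free social behavior, from binarized calcium-event rasters
and multi-animal tracking. This note documents the statistical procedures, the
choices made where the standard workflow leaves them open, and what the bundled
synthetic generator does and does not emulate.

## Reference frames

Every cell is analyzed in four coordinate systems built from the same session:

| frame | coordinates | cell category |
|---|---|---|
| `self_allo` | imaged animal in the arena | place cell (selfPC) |
| `other_allo` | partner in the arena | social-place cell (socialPC) |
| `rel_allo` | partner − self, arena-fixed axes | allocentric social-vector cell (alloSVC) |
| `rel_ego` | partner − self, axes rotated by −(head direction) | egocentric social-vector cell (egoSVC) |

Axes are x-right / y-up in cm, angles counter-clockwise from +x in radians.
In the egocentric frame "directly ahead" is +x and "left" is +y; all statistics
are invariant to this axis convention. Relative positions live in an
*effective arena* of twice the physical linear extent (four times the area),
binned twice as coarsely so both map types have the same grid size.

Relative coordinates are anchored on the tracked body point of the imaged
animal by default (`config.relative_origin`); a head anchor is a drop-in
replacement when head tracking is available, and none of the statistics depend
on the choice beyond a few centimetres of offset.

## Maps, information, fields

Trajectories are cleaned (non-finite, flagged, or out-of-arena samples marked
invalid and linearly interpolated) and smoothed with a centered 15-point mean
filter; head direction is smoothed circularly by averaging unit vectors over
the same window. Invalid frames are excluded from all map accumulations, never
imputed.

Rate maps use 2 cm bins in physical frames and 4 cm bins in the effective
arena. The rate in a bin is events/occupancy; smoothed maps are
G(counts)/G(occupancy) with a 2-D Gaussian kernel of sd 2 bins (zero-padded
boundaries), i.e. a convolution whose kernel mass is renormalized over visited
bins *weighted by time spent*. This is the convention of the classical
place-cell toolboxes; it preserves constant maps exactly and keeps bins visited
for a single frame from injecting ~30 Hz spikes into the map. Bins with less
than `min_occupancy_s = 0.1 s` (3 frames) of occupancy are flagged unreliable
and treated as unvisited by information, correlations and field detection;
stored occupancy/count arrays still cover every bin, so event and time totals
are conserved.

Spatial information per event is

    I = Σ_i p_i (λ_i/λ) log2(λ_i/λ),

with p_i the occupancy distribution over analyzed bins and λ_i the (smoothed)
bin rate. λ is computed as Σ_i p_i λ_i from the same map rather than as total
events / total time: on raw maps the two are identical, and this choice makes
I exactly a weighted Kullback–Leibler divergence, hence non-negative to machine
precision with equality iff the rate is constant. Information is computed on
smoothed maps by default (`config.info_on_smoothed` switches to raw maps).

Place fields are local maxima of the smoothed map above 0.5 Hz; a field's area
is the 4-connected component of bins above 60% of its peak, and overlapping
candidates merge into the higher peak. Radial profiles count field peaks in
5 cm rings around the origin, normalized by ring area, with coverage measured
as the fraction of each ring's bins that were (reliably) visited.

## Classification

A cell joins a category when the information of its map exceeds the 95th
percentile (linear-interpolation convention) of the information distribution
over 1000 circular time-shifts of its event train, *and* the Pearson
correlation of its two half-session maps exceeds 0.3 (applied per frame of
reference). Shifts are drawn uniformly with a 20 s floor so no shuffle sits
near identity. Categories are non-exclusive. Shuffle streams are seeded per
(cell, frame) from the session seed, so results do not depend on processing
order. Cells with zero events are excluded with an explicit status.

The overlap index of two categories is n_AB / (N p_A p_B) with p_X = n_X/N,
tested with an exact two-tailed binomial test at probability p_A·p_B.

**Shuffling-in-place** is the false-positive control for social categories: the
physical arena is divided into 10 cm bins; for each bin the frames the imaged
animal spent there are stitched in temporal order and the events on them are
circularly shifted by a random amount at least 5 s away from identity (the
maximum-distance shift when a bin's coverage is too short), then re-placed.
The self-place map at 10 cm resolution is preserved exactly by construction;
relative-position tuning is destroyed. Note the control is not perfectly
neutral at 2 cm resolution: moving an event to another visit of the same 10 cm
bin adds ≈2·(10²/12) ≈ 17 cm² of positional variance, which for a field of
σ = 8 cm (σ_eff² ≈ 80 cm² after smoothing) costs ~0.27 bits, an information
drop of 11–15%. For the broad fields typical of real CA1 data the same control
is proportionally gentler.

## Decoding

Position in any frame is decoded by a naive-Bayes rule under independent
Poisson event counts: the decoded bin maximizes
log P(X) + Σ_i n_i log f_i(X) − τ Σ_i f_i(X), with f_i the training-fold
smoothed rate maps floored at 10⁻⁴ Hz, P(X) the training occupancy prior, and
τ = 0.5 s sliding windows with one-frame stride (window centered on the
decoded frame; ties resolve to the lowest row-major bin). Cross-validation
uses five *consecutive* session segments; windows are decoded only inside
their held-out segment. Errors are mean Euclidean distance between the decoded
bin center and the true position, in cm. Baselines re-run the entire pipeline
(map fitting included) on sessions whose positions were circularly displaced
in time — the stronger null compared with shuffling only the test positions.
Cross-referent decoding fits on one partner's relative positions and transfers
to the other partner in full.

## Remapping and identity

Identity coding is probed with split-half map correlations where the two
half-maps may use the same or different referents; both maps share the
effective-arena grid so they are directly comparable. Across contexts of
different geometry, similarity is the dot product of population vectors: each
cell's mean event rate per condition, normalized per cell by its maximum over
the conditions compared (the union of the session halves entering the
comparison), then per condition by the Euclidean norm — the cosine of the
angle between population activity patterns.

## Pursuit task

On the annular track the geometry collapses to the signed angle α between the
two animals' position vectors, measured along the track in the imaged animal's
travel direction: unwrapped to [0°, 360°) for counter-clockwise travel and
negated ((−360°, 0]) for clockwise travel, so α near 0 means "partner just
ahead". Travel direction is the sign of the angular velocity about the center,
boxcar-smoothed over 0.5 s, with a 3°/s dead-band inside which frames inherit
the last confident direction. Angle maps have 24 bins of 15° per travel half,
occupancy-normalized and circularly smoothed within each half (Gaussian,
σ = 1 bin).

Per-map peak metrics: the signal region is the contiguous run of bins around
the peak (circular within its half) at ≥50% of the peak rate; half-width is
its angular extent and the signal fraction the share of total map activity it
contains (the signal-to-noise activity ratio is f/(1−f)). A region spanning a
whole half flags the map untuned. The population autocorrelogram correlates
the stacked maps with per-half circular shifts from −180° to +180° (Pearson,
both halves pooled); its AUC is the *mean* correlation over shifts so values
are comparable across shift grids. Naive/trained session labels follow the
latency rule: the first session whose median trial latency falls below 30% of
the previous day's maximum starts the trained phase; the first session is
always naive. Experience curves pool angle maps over non-overlapping groups of
5 consecutive sessions and report the Pearson correlation of AUC against group
index.

## Synthetic sessions

The generator emulates the study conditions end to end: 10-minute sessions at
30 Hz in a ⌀70 cm arena (squares and annuli supported), two or three mice,
head direction aligned to motion with Gaussian noise (sd 0.25 rad). Foraging is
a correlated random walk — heading random walk of 1.6 rad/√s, mean-reverting
speed around 8 cm/s, boundary avoidance by turning toward the arena interior —
and a partner can be biased toward the imaged mouse (`attraction`, default
0.3, the fraction of heading re-oriented per 0.5 s). Pursuit sessions place a
leader at fixed angular speed (60°/s, direction random per trial) and a
follower that wanders for the trial's latency before locking a 20° trailing
gap.

Cells carry Gaussian tuning fields in any frame (per-partner gains in [0, 1]
for social frames) or Gaussian tuning in α for the annular task; events are
Bernoulli-per-frame thinnings of rate·Δt, matching the binarized raster the
analysis consumes. Default planted populations use peak 1 event/s, field
σ 8 cm, baseline 0.02 events/s, with relative-frame field centers inside a
25 cm disc where relative positions are visited densely. The "trained"
pursuit phenotype is sharper tuning (σ 15° vs 40°) with suppressed off-field
activity (baseline 0.01 vs 0.05 events/s, peak raised to 2.5 events/s to keep
mean event rates comparable) — training concentrates activity in the signal
region without recruiting more cells or changing rates. Identity simulations
use 3 events/s peaks so that 60-cell populations support window-level
decoding. One session seed fans out to per-component seeds via `SeedSequence`
spawn keys: adding cells never perturbs trajectories, and per-cell event
streams are independent of ordering.

What the generator does **not** emulate: calcium-indicator dynamics (rise and
decay kernels, amplitude variation), pose-estimation noise and identity swaps,
behavioral structure beyond proximity attraction (no ethogram), non-Poisson
spike-train statistics, and cross-session cell-registration errors (identity
mappings are taken as given). Passing tests therefore validate the analysis
chain — not the upstream extraction pipeline — under idealized event
statistics.

## Problem sizes and numerics

Validation simulations use sizes chosen to estimate each property with useful
precision on a single CPU: null calibration pools 200 untuned cells × 20
generator seeds × 1000 shuffles; recovery pools 4 sessions × 50 planted cells
per category; decoding-power checks use 50 cells against 100 position-shuffle
baselines; the pursuit contrast uses 40 cells per phenotype and 1000
label shuffles. Batched shuffle information runs in single precision (the
null distribution's 95th percentile is insensitive at the 1e-6 level); true
map statistics stay in double precision. Gaussian filtering truncates at 4 sd.
Degenerate inputs (all-invalid trajectories, zero-event cells, empty
categories, all-zero angle maps) raise typed errors or return explicit
NaN/skipped statuses rather than silent zeros.

## Known limitations

- The alloSVC category inherits the false-positive coupling with selfPC near
  arena borders discussed in the source analyses; this package quantifies it
  (overlap index, shuffling-in-place) but does not correct for it.
- The minimum-occupancy threshold trades a small amount of rim coverage for
  map reliability; radial coverage profiles reflect *reliable* coverage.
- No multiple-comparison correction is applied across cells, matching the
  upstream workflow.
- The annular α reduction assumes head direction roughly tangent to the track;
  sessions violating this should be analyzed with the 2-D egocentric maps
  instead.
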