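# Methods

## The assay and its quantities

The pipeline quantifies wind-oriented navigation of groups of walking
flies (typically ~20 per movie) in a circular four-quadrant olfactometer
arena of radius R = 50 mm, filmed at 30 frames/s for 60 s.  Air enters
through four peripheral arms (100 mL/min each) and leaves through a
central suction hole (400 mL/min), so the local wind direction at every
point is radial: *upwind is radially outward*.  Facing the arena center
is therefore ±180° to upwind.  Odor pulses are delivered by switching
solenoid valves; the odor reaches the flies about 3.5 s after the valve
switch (tubing dead volume plus arena fill), so odor epochs are aligned
to `valve_on + 3.5 s`.  LED (optogenetic) epochs act at the switch time.
Epochs are half-open, `[onset, onset + duration)`, frames are 0-based and
the time of frame k is k / frame_rate.

### Area-normalized radial index

The area of a radial bin grows with r² (the 40–50 mm ring has nine times
the area of the 0–10 mm disk), so raw radial position over-weights the
periphery.  All radial statistics therefore use the squared normalized
radius (r/R)².  Under area-uniform occupancy E[(r/R)²] = 1/2 and
RMS(r/R) = 1/√2 ≈ 0.7071, which is the null against which *upwind
displacement* — the population mean of (r/R)² minus its value at
stimulus onset — is read.

### Upwind angle and onset kinematics

The signed angle to upwind is α = wrap(upwind_bearing − heading) in
(−180°, 180°], counterclockwise positive; with inward flow the upwind
bearing at (x, y) is atan2(y, x), with reversed flow it is the opposite,
and with wind off α is undefined (NaN, never an exception; the same
applies at the exact center where the radial bearing is ambiguous).
Heading change per frame is the wrapped first difference; forward speed
is the frame-to-frame displacement projected on the body axis at the
earlier frame (it may be negative when backing; the unprojected speed is
also emitted).  No smoothing is applied to any derivative — windowed
statistics already average over frames, and smoothing choices are left
to callers.

The *cumulative turn at onset* sums wrapped heading changes over the
first 10 frames (333 ms) of a stimulus.  The folded variant multiplies
that sum by sign(α at onset), so positive values mean rotation toward
upwind on either side; a fly exactly facing upwind folds to 0.  Folding
the summed rotation (rather than differencing |α| endpoints) keeps
left- and right-starting flies comparable and preserves the magnitude of
overshooting turns.  Curves against initial angle are smoothed with a
±30° circular window on a 10° grid; empty bins are NaN with count 0.

### Gates and exclusion rules

Tracking artifacts — a single-frame displacement of more than 5 mm or a
wrapped heading change of 180° or more — mark the surrounding data
invalid.  Two notes on the heading rule: wrapped differences cannot
exceed 180°, so the operative trigger is a change *reaching* 180°, the
signature of a tracker body-axis flip whose direction is ambiguous; and
a 10⁻⁹-degree numerical guard keeps an exactly-180° flip detectable
despite floating-point wrapping.  By default only the two frames
bounding a bad step are invalidated; passing analysis windows widens the
exclusion to the whole window containing the artifact, which is the unit
used when a trajectory is dropped from a windowed analysis.

Onset-response analyses use only flies at least 3 mm from the wall
(inclusive; the bound is an argument so a strict reading is one flag
away) and, for the canonical turning statistic, only flies initially
oriented 90–150° from upwind on either side, where a directed turn is
unambiguous.

### Return probability

For each reference time time0 on the frame grid, a fly *returns* if it
moves more than 10 mm away from its time0 position and later comes back
to within 3 mm of it, both within the 15 s after time0 (excursion before
re-entry).  For a 60-s movie time0 spans 0–45 s.  The reported profile
is the fraction of flies returning at each time0.

### Preference index and reciprocal averaging

Quadrants are the four 90° sectors delimited by the arena diagonals,
indexed counterclockwise from the sector centered on +x (the boundaries
are conventional; the index only ever contrasts diagonal pairs).  Per
frame, PI = (N in the odor-one diagonal pair − N in the other pair) /
N_total, averaged over the test window (by default the final 30 s of the
recording).  Reciprocal experiments swap the odor roles between the
physical quadrant pairs; with both PIs signed toward the same physical
pair, the CS+-aligned mean (PI_a − PI_b)/2 cancels any static position
bias and innate odor preference common to both runs.

### Activation-screen matrix

Each driver line's movie is reduced to five parameters — upwind
displacement, mean cos α, angular velocity, forward speed, and return
probability — in 2-s bins tiling [onset − 4 s, onset + 20 s] around a
10-s stimulation (2 pre, 5 during, 5 post; counts configurable).  Each
(parameter, bin) cell is standardized across all screened lines
(including the empty-driver control), z = (value − mean)/SD with the
sample (n − 1) SD — across-lines is the population that makes a screen
heat map comparable, and with a handful of lines the sample SD is the
defensible choice; both facts are recorded in the matrix metadata.
Zero-spread cells get z = 0 with a flag.  Hit ranking orders lines by
mean z over chosen bins; it is descriptive and deliberately applies no
multiplicity correction.

Population means are computed per movie first and across movies second
(each movie is one replicate); per-fly pooling is an explicit flag for
trajectory-level analyses, as is the unit used for SEM bands.

## The synthetic-fly generator

Real raw trajectories for this assay are not distributable, so the
package ships an agent-based generator that emulates their statistical
structure.  Each fly is a discrete-time correlated random walk at the
video frame rate: heading accumulates Gaussian noise (default SD
6°/frame, 180°/s RMS angular speed — brisk but within the range of
walking flies), speed is drawn per fly from N(10, 3²) mm/s (floored at
0.5), and flies start area-uniform with uniform headings.  On top of
the walk:

* **startle** — for the first 10 frames (333 ms) of each stimulus an
  extra half-normal turn of scale `startle_gain_deg` (default 15°/frame)
  is added, directed toward upwind with probability
  `startle_upwind_bias` (default 0, i.e. non-directional, as in
  empty-driver controls);
* **upwind steering** — during the stimulus the heading gains
  `upwind_turn_gain · sin(α)` deg/frame and the speed gains
  `speed_mod_gain · cos(α)` mm/s; sin/cos are the minimal smooth forms
  with the right symmetry (zero facing up-/downwind, maximal broadside),
  and both default to 0;
* **post-offset homing** — for 15 s after stimulus offset the heading
  gains `return_gain · sin(bearing-to-offset-location − heading)`
  deg/frame toward the fly's own position at offset (suspended within
  1 mm of it), default 0.

Wind-referenced terms follow the configured wind mode and are inactive
with wind off; startle and homing act regardless.  Walls default to
`turn_away` (the fly stops for one frame and its velocity is reflected
off the tangent); `reflect` additionally mirrors the position, which
keeps long-run occupancy closer to uniform and is used for
null-distribution checks.  One integer seed drives a single generator
stream, so identical inputs give byte-identical tracks.

Artifact injection adds Poisson-sampled tracking errors for filter
validation: position jumps of 6–9 mm toward the center (guaranteed
in-bounds and above the 5-mm rule) and body-axis flips placed exactly
180° off the previous frame's heading (detectable under wrapped
differencing).  Ground-truth frames are recorded in provenance, giving
the filter a recall-1 / false-positive-0 oracle on clean kinematics.

What the generator does *not* emulate: odor-plume structure and
concentration dynamics, inter-fly interactions and collisions, pausing
and grooming bouts, wall-following attraction, and body-pose detail.
Passing tests therefore demonstrate that the *analysis* is correct and
well-calibrated on data with the assumed structure — not that real flies
behave like the model.

## Numerical choices and scales

* Angles wrap to (−180°, 180°] with the boundary mapped to +180°; a
  heading change of exactly 180° is sign-ambiguous and treated as an
  artifact trigger.
* Undefined values (α with wind off or at the center, derivatives at
  series ends, empty bins) are NaN and excluded by nan-aware reduction,
  never silently zeroed.
* The on-disk track format writes 6 decimal places; a read/write round
  trip is byte-stable and preserves all metrics to ≤ 10⁻⁶.
* Validation suites run at sizes a laptop handles in minutes, chosen as
  the smallest that leave clear statistical margin: oracle-equivalence
  checks use 1000 short tracks per rule (the return-metric check with a
  shortened 2-s window so excursions are common); turn-gain recovery
  uses 400 trajectories at gain 3°/frame, where the sinusoid fit has
  ≈ 5% standard error against a 15% acceptance band; the screen check
  uses 12 lines × 20 flies × 20 seeds.  The recovered turn-gain
  amplitude runs a few percent low by construction: steering feeds back
  on α within the 10-frame window, pulling |sin α| down as flies align.

## Known limitations

* The exclusion unit for tracking errors ("the trajectory" in the
  verbal rule) is interpreted per analysis window, not per movie; both
  behaviors are available.
* Whether the original forward-speed statistic was projected or total
  speed is unknowable from the assay description; projected is the
  default and both are emitted.
* The screen's pre/post bin counts are layout choices (2 pre, 5 post by
  default) and configurable.
* Return-probability denominators count flies valid at time0 only; a
  fly lost mid-window still counts against a return.
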