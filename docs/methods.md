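# Methods

## The event-chain representation

An action is represented by the ordered sequence of *qualitative* changes
in the relations between scene objects. Five roles suffice for
single-handed manipulations: the Hand, the Ground, and up to three
abstract objects numbered by the order in which they enter the action.
Concretely, an unroled object receives the next free role (O1, then O2,
then O3) at its first touch **or** un-touch transition with an
already-roled non-ground entity; O1 must be born by the hand's first
touch. Before its birth an object's rows are undefined (`U`), and objects
that never interact (distractors) never appear. With this convention the
start column C0 — hand far away, nothing touched, no object in being — is
literally identical across all actions, and role assignment is purely
observational: no object identities are used anywhere downstream.

The table has 10 pair-rows × 3 channels:

| channel | symbols | meaning |
|---|---|---|
| TNT | `T N A U` | surface gap ≤ `contact_distance` |
| SSR | `Ab Be R L F Ba In Sa Bw AR To ArT O A U` | static spatial relation |
| DSR | `MT HT FMT GC MA S Q A U` | dynamic spatial relation |

`A` (absent) is a legal symbol in every channel but the scripted world
never produces it: unborn roles stay `U` and a hand that has left the
scene reads `N/O/Q` (not touching, very far). This keeps C0 canonical.

## Geometric predicates

Objects are axis-aligned boxes in a viewer-centric frame (+z up, +x
right, +y back). The original predicate definitions and numeric
thresholds are not published in the available text, so the following are
the package's own declared stand-ins, chosen to reproduce the documented
seven-change structure of the hiding action; all are configurable
(`RelationThresholds`):

* **Touching**: box surface gap ≤ `contact_distance` (default 5 mm).
* **Very far** (`O`/`Q`): center distance (box gap for Ground pairs)
  beyond `very_far_distance` (1 m).
* **SSR**, first match wins: touching + footprint-contains (margin 5 mm)
  → `ArT`; fractional volume containment ≥ `containment_overlap` (0.5) →
  `In` / `Sa`; footprint-contains without touch → `AR`; touching with
  dominant vertical displacement → `To` / `Be`; center within the
  extent-inflated segment between two other role objects → `Bw`;
  otherwise the dominant displacement axis (`Ab/Be/R/L/F/Ba`), ties
  broken by the fixed priority Ab > Be > L > R > F > Ba. Displacements
  are quantized to 1 µm so ties are exact and deterministic. Ground
  pairs are special-cased as a support plane: `To` when touching, else
  `Ab` — the ground is never "beside" anything.
* **DSR** from forward-difference velocities (optional moving-average
  smoothing, default off for noise-free input). Ground pairs: still →
  `S`; vertical rate beyond ±`approach_epsilon` (2 cm/s) → `MA`/`GC`;
  otherwise (horizontal transport) → `FMT`. Movable pairs: both still →
  `HT`; relative speed < `speed_epsilon` (1 cm/s) → `MT`; range-rate
  beyond ±`approach_epsilon` → `GC`/`MA`; else `S`.

**Column segmentation.** A physical change-moment (a grasp, a placement)
touches several relations across neighbouring samples: the contact
boundary is crossed one or two samples away from the motion keyframe it
belongs to. A column therefore opens at the first changed sample and
absorbs every change within `fold_window` (0.15 s) of its opening, each
cell taking its state at the end of the folded group; a group that nets
out to no change produces no column. Timestamps are the fold-group
opening times, in seconds from action start; the final column (the hand
leaving the scene's far field) defines the total action time Tot.

## Similarity and prediction

The similarity measure is exactly the padded grand-mean construction:
per pair and column, channel indicators D¹–D³ (0 iff equal, with `U` and
`A` ordinary symbols), per-cell `diff = √(D¹+D²+D³)` ∈ {0, 1, √2, √3},
last-column padding of the shorter table to p = max(n, m), Dis the mean
of the 10 × p matrix, Sim = (1 − Dis)·100. Sim may be negative (bounded
below by (1 − √3)·100 ≈ −73.2) and is reported unclipped. C0 is excluded
from all comparisons: it carries no information.

Calibration draws m = 20 members per repeat (without replacement, capped
at the class size), computes all ½m(m−1) = 190 pairwise similarities,
and averages 20 repeats (3800 values) into the class threshold Θᵢ —
classes genuinely differ in self-similarity (within the synthetic corpus,
Θ ranges from ≈ 81 for chopping, whose chip-direction varies across
variants, to 100 for classes whose variants differ only in timing).

Online prediction compares the growing prefix C1..Ck against the
*equally long* prefixes of 20 sampled members of every surviving class
(prefix-truncation is the minimal reading of the cumulative rule; the
padding rule applies when a member is shorter). Elimination (mean Sim
below Θᵢ) is permanent; one survivor → recognized at that column; none →
"unrecognized"; several at stream end → "ambiguous" with the survivor
list (no forced choice). A `deterministic` mode compares against all
members instead of sampling. T(γ) is the deciding column's timestamp,
and P = (1 − T/Tot)·100.

## The synthetic block world

The generator emulates tabletop demonstrations with cube-like objects:
the hand enters from above, manipulates one or two blocks (plus a
detachable chip for cutting/chopping), and leaves, so every action starts
and ends hand-free. Trajectories are piecewise-linear keyframe tracks
sampled at 40 Hz; jerk realism is irrelevant because only relational
predicates are consumed downstream.

Variants randomize what the encoding should be invariant to: layout
translation on the tabletop, layout orientation along one of the four
compass axes, 0–3 distractors (rejection-sampled away from the workspace
strip), and the durations of the approach / hold / gesture phases (a
global tempo factor ~N(1, 0.18) clipped to [0.7, 1.4] times per-phase
jitter U(0.92, 1.08), snapped to the sampling grid). Transport phases run
at fixed speeds: this makes the event-column *sequence* a class property
(direction symbols aside) while event *times* vary — mirroring the
observation that same-class demonstrations are similar but rarely
identical. Phase durations are tuned so that each class's recognition
moment and total duration land at the measured human-demonstration
averages (e.g. the hiding action: recognition at its 4th change-moment,
8.3 s into a 13.8 s action; taking down: 3.3 s of 11.7 s).

Choices the design left open, decided here:

* The hiding cover is a tall hollow box that ends up *around* the block
  (`ArT`) and resting on the ground — which also makes hiding
  distinguishable from stacking, and taking-down distinguishable from
  uncovering, under the touch-only projection, as in the original
  recordings.
* Uncovering includes a brief "reveal" pause with the cover held aloft;
  its third column is then a pure role-birth column, structurally
  separate from taking-down's lift-and-carry column.
* The chip cut off a slab slides away from the knife's side; shaking is
  two vertical oscillation cycles (each stroke flips the ground-pair
  DSR); stirring is two revolutions entered on the stirring circle so the
  spoon–bowl distance stays constant.

What the synthetic world does **not** emulate: human kinematic
variability (smoothing is off by default), orientation changes (poses
carry quaternions for the on-disk format, but predicates use axis-aligned
extents), occlusion or perception noise (input is ground truth, as in a
VR setup), and the continuous range of layout orientations (four compass
axes only — arbitrary rotation would move direction-symbol boundaries
mid-action). Passing tests therefore show that the pipeline implements
the representation, measure and predictor correctly and that they behave
as expected under controlled geometric/timing variability — not that the
predictor would reach the same accuracy on human motion-capture data.

Under the touch-only (SEC) projection this world makes laying and
shaking *identical* — the oscillation is purely dynamic — so SEC-mode
classification reports them as ambiguous rather than picking one; the
full encoding separates them at the first oscillation stroke.

## Scheduling

An agent may start the next chain action once (a) its own previous action
has ended and (b) the predecessor action has become predictable:
start_k = max(own free time, start_{k−1} + prediction moment_{k−1}).
Savings are measured against the sequential sum of durations and
expressed as a chain-level P. The Monte-Carlo driver samples per-action
(duration, prediction moment) pairs from the packaged timing table
(Gaussians truncated to 0 < moment < duration, via rejection sampling),
cycling through all 120 orderings of the five chain actions by default.
10⁵ draws reproduce the sequential baseline at 62.7 ± 5.2 s and order the
modes full-encoding < touch-only < sequential, as the earlier prediction
moments imply. Scene-geometry modulation of robot execution times is out
of scope; durations come from the timing distributions alone.

## Numerical notes

* All randomness flows through `numpy.random.Generator`; per-variant
  streams derive from one master seed via `SeedSequence(seed,
  spawn_key=(class_index, variant))`.
* The fold-window comparison carries half-sample slack so grid float
  rounding cannot flip a boundary fold.
* Writers emit fixed 6-decimal floats; written files are byte-stable and
  the trajectory round-trip tolerance matches that precision.
* The online predictor uses an integer-coded similarity path that is
  asserted (at 10⁻¹² ) against both the readable implementation and an
  independent triple-loop evaluation.
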