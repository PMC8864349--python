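# Methods

## World, units, state

The world is planar (Cartesian metres); headings are degrees
counter-clockwise from +x and positive angular velocity is a left turn.
Each prey agent carries position, heading, speed, an individual cruise
speed (drawn once per run, N(18, 0.5²) m/s), an individual baseline
escape tendency (drawn once, U[1.25·10⁻³, 10⁻²] per perception update),
a reaction clock, and possibly an active escape manoeuvre. The predator
carries kinematics plus its hunting-cycle phase and phase timer.

Integration uses a 0.05 s step. Positions advance every step; steering
is refreshed per agent only when its own reaction clock (period 0.1 s,
initialized uniformly staggered) expires, so perception is asynchronous.
Steering forces are lateral accelerations: the heading changes at
`a_lat / v` rad/s, capped at 300 °/s. Constant lateral steering thus
produces circular motion of radius v²/a, which the tests verify against
the closed form.

## Coordination

A bird interacts with up to its 7 nearest conspecifics within 50 m
(equal distances break toward the lower id). Forces:

* **Alignment** (weight 12 ... 18 m/s², default 18): unit vector along
  the neighbours' mean heading. Strongest force, per the empirical
  ordering for pigeons.
* **Attraction** (weight 14): toward the neighbourhood centre of mass,
  scaled linearly with distance-to-COM up to a 12 m saturation span.
  The linear ("spring") region is essential: with a constant-magnitude
  unit-vector force, interior birds receive direction-flipping noise
  (their COM nearly coincides with them) and a bird near a forming gap
  feels no extra pull, so flocks of 27–34 cleave irreversibly. The
  spring makes re-binding force grow with the gap while staying gentle
  at rest spacing.
* **Separation** (weight 9): away from the single closest neighbour,
  tapering linearly to zero at the 3 m separation radius. The taper
  removes bang-bang impulses at equilibrium spacing, which otherwise
  randomize headings and destroy long-range order in large flocks.
* **Speed control**: linear drag (2 s⁻¹) toward the bird's own cruise
  speed plus a catch-up acceleration toward the neighbourhood COM,
  saturated at ±5 m/s² (full strength at 1.5 m longitudinal offset).
  The catch-up term is signed — birds brake when their neighbours fall
  behind. Without braking, heterogeneous cruise speeds sort the flock
  longitudinally until the front detaches; this was the dominant
  fission mode in early versions.

Flocks initialize in a disc whose radius scales with flock size
(≈1.1·√n m, i.e. realistic density), headings near-aligned with 5° sd
jitter. A 15 s predator-free settling period precedes every recorded
cycle so that release-transient artifacts (violent condensation of an
over-spread disc) do not contaminate the measurements.

With these defaults, predator-free flocks of 8–10 never split over 60 s
flights, while flocks of 27–34 fission only occasionally — mirroring
the empirical pattern that unthreatened small flocks do not split while
larger ones sometimes do.

## Predator

One predator runs a fixed 60 s cycle split 0.5 / 0.17 / 0.33 into:

* **Pursuit** — tail-chase: the predator aims at the flock centroid
  plus a slowly weaving lateral offset (amplitude 25 m, period 6 s,
  imitating the wandering aim of a piloted pursuer) and holds its 30 m
  range by speed modulation (gain 0.5 s⁻¹, clamp 0.6–1.5× the 20 m/s
  pursuit speed). The weave matters: a pursuer aimed dead-centre keeps
  its heading line through the flock's middle, which pushes the two
  halves of the flock toward opposite escape sides and guarantees
  fission. A wandering aim gives the whole flock one coherent escape
  side at any moment.
* **Attack** — steers straight at the closest bird at 35 m/s.
* **Retreat** — steers away from the centroid at 25 m/s until 300 m
  away, then holds heading.

Turning is capped at 120 °/s; speed relaxes toward the phase target at
2 s⁻¹. Catches are not modelled.

## Escape rules

**Continuous avoidance.** Each non-manoeuvring bird receives a pure
lateral steering force on the side that rotates its heading *away from
the predator's heading* — the same directional rule as the discrete
manoeuvre, of which this force is the continuous counterpart.
Degenerate geometry (parallel or anti-parallel headings) breaks the tie
away from the predator's position, then left. The magnitude is
`w · min(exp(−d/d₀), 0.35)` with w = 12 m/s² and d₀ = 30 m: the
exponential localizes the response near the predator, and the
close-range cap prevents the attack phase from "blasting" nearby birds
apart in opposite directions. An early design followed the common
formulation — force perpendicular to the predator's heading on the side
of the bird's position — but that rule bisects any flock the predator
approaches from dead astern (the standard pursuit geometry) and
produced constant catastrophic fission; the heading-based rule couples
with alignment into coherent whole-flock turns instead.

This coupling is also the turn-propagation mechanism: an initiator's
manoeuvre shifts the flock's mean heading a few degrees; every bird
then shares the same sign of heading-offset from the predator's
heading, the shared avoidance force amplifies the deflection, and the
pursuing predator re-aims, sustaining the turn. Collective turns are
therefore genuinely seeded by initiators and amplified by the shared
escape tendency, with no manoeuvre-copying rule.

**Discrete manoeuvre.** At each perception update an un-manoeuvring
bird starts a manoeuvre with probability
`p = tendency · exp(−d/d₀)` (clamped to [0,1]; identically zero without
a predator), evaluated per perception update so trigger rates are
independent of the integration step. Angle (degrees) and duration
(seconds) are drawn independently from Gamma(2, 30) and Gamma(3, 0.6) —
median turn ≈ 50° over ≈ 1.6 s with right-skewed tails, the calibration
target for pigeon escape turns. The signed rate `±angle/duration`
rotates the bird away from the predator's heading. While manoeuvring, a
bird applies only its manoeuvre turn rate and the cruise-speed drag:
coordination *and* the continuous avoidance force are suspended (the
manoeuvre *is* the escape response); one manoeuvre at a time, new
triggers during one are ignored. On completion the bird's perception
refreshes immediately.

## Detection

Detectors use positions only; simulated headings are ignored, so
simulated and GPS-like tables are treated identically.

* **Turn segmentation**: headings from successive displacements
  (stationary samples carry the last moving heading forward);
  per-sample angular velocities below a 0.5 °/s dead band are
  sign-neutral. A neutral stretch bridging two same-sign turning runs
  merges into them (sampling noise would otherwise fragment turns); a
  neutral stretch at the ends or between opposite-sign runs stands as
  its own straight segment (a blanket absorption rule would swallow
  genuine straight flight between opposite turns). Segments are
  labelled straight below a 10 °/s average angular velocity (the
  threshold is a config field, so the 5/10/15 °/s robustness check is a
  one-line change) and tile the trajectory to one sample period.
* **Splits**: per frame, agents partition into connected components
  under ≤ 10 m adjacency; the largest is the main flock (ties: the
  component holding the lowest id). An excursion (no main-flock member
  within 10 m) must last ≥ 2 s; departures starting within 1 s of each
  other that are mutually connected form one sub-flock event (the
  "simultaneously" of the definition, given a tolerance); merges are
  recorded when the criterion re-inverts.
* **Centrality**: distance to the flock centroid, normalized by the
  mean over all individuals and times of the same flock-size class
  (small ≤ 10 birds, large otherwise), so normalized centrality
  averages 1 within each class.
* **Outcome attribution**: inside the window from manoeuvre onset to
  its end plus 2 s — `split` if a split event starting in the window
  contains the initiator; else `collective_turn` if the main-flock
  centroid has a turn-labelled segment of matching sign overlapping the
  window; else `none`. Only initiators inside the main flock at onset
  are classified (`excluded` otherwise), and a given split event or
  centroid turn is credited once, to the earliest-onset manoeuvre. The
  window and crediting rule are design choices; the underlying
  definition states intent, not an algorithm.

## Batch experiments and statistics

A batch runs independent 60 s cycles (fresh flock each time; sizes
rotate through the empirical multiset 8, 10, 27, 34; per-cycle seeds
spawned deterministically from one base seed) and pools all events into
one dataset *before* any median split — trait labels and the centrality
normalization are defined on the pooled distribution. Per-flight rates
are summarised by the across-flight median (the distributions are
highly skewed). Contrasts are Pearson chi-squared on the 2×2
trait-level × outcome table without continuity correction (configurable),
`none`/`excluded` outcomes excluded from the table but reported, and
relative effects are ratios of conditional probabilities minus one
(e.g. (P(split|high) − P(split|low)) / P(split|low)), since the
relative reading of the reported percentages is the one adopted.
Centrality distributions across outcomes and predator-vs-control
per-flight metric distributions are compared with two-sided two-sample
Kolmogorov–Smirnov tests.

## Calibration

Unavailable model constants (force weights, reaction and speed-control
constants, gamma and probability parameters, predator quantities) are
exposed in `SimConfig` and documented as assumptions. They were fixed
by two requirements, in order: (1) predator-free cohesion across the
empirical flock sizes with realistic speed regulation, and (2)
with-predator turning activity at the empirically reported level
(roughly half of flight time spent turning, turning rate ≈ 0.15 s⁻¹,
collective turns at least as frequent as splits). The initiator-effect
magnitudes that the package's replication script reports are emergent
under those conditions, not fitted.

## Synthetic fixtures

`flockescape.fixtures` generates kinematically consistent 5 Hz tracks
with known ground truth: straight flight, constant-rate arcs, scripted
turn sequences, solitary and sub-flock departures, and whole-flock
turns, with optional additive Gaussian position noise. Ground-truth
split times are computed from the generated geometry (the moment the
departing group's last ≤ 10 m link to the rest breaks), not by the
detector under test. These fixtures emulate the *structure* of GPS
flock data, not its full messiness: no GPS dropouts, no per-logger
bias, no altitude leakage, and scripted rather than emergent kinematics
— so passing detector tests demonstrates correctness of the rules'
implementation, not robustness to every field artifact.

## Problem sizes and numerical notes

Replication batches use 100 cycles per base seed across five seeds
(2000 simulated minutes in total), a scale at which the headline
contrasts are stable to a few percentage points while a full run
completes in minutes on one core. Determinism: one master seed spawns
independent sub-streams (initialization vs escape sampling; per-cycle
children) via `numpy` `SeedSequence`, and reruns are bit-identical.
Degenerate inputs are defined explicitly: zero-displacement samples
carry headings forward; a bird exactly on the predator's heading line
escapes left; an initiator exactly at the centroid is labelled
`outwards`; main-flock ties break by lowest id.

## Known limitations

The world is 2-D; banking, altitude and aerodynamics are out of scope,
as are predator catches, multiple predators, and predator learning.
Sub-flocks of eight or more birds are topologically self-contained
(their seven nearest neighbours are all inside the sub-flock), so once
such a group departs it does not rejoin; empirical flocks eventually
re-merge through homing motivation, which the model does not represent.
The exact forms of the manoeuvre-probability distance function and the
original coordination constants are assumptions; all are config fields
so alternative calibrations can be swapped in without code changes.

Under the default calibration the initiator effects are qualitatively
robust but quantitatively strong: the flock's followability boundary
(the fastest turn neighbours can track, set by the alignment weight)
lies close to the median manoeuvre angular velocity, so above- and
below-median manoeuvres segregate sharply into unfollowable and
followable ones, and the replication script's sharp-turn and
centrality contrasts come out several-fold stronger than under the
original (unavailable) parameterization. Likewise, attack-phase flash
fissions of the larger flocks raise the sub-flock share of splits
above the original model's level. These magnitudes should be read as
properties of this calibration, with the directions of all three
effects the robust result.
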