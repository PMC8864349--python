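# flockescape

Agent-based simulation and trajectory analysis of collective escape in
homing-pigeon flocks hunted by an aerial predator.

When a small bird flock is chased, two collective patterns dominate:
**collective turns**, in which the whole flock changes heading together,
and **splits**, in which one bird or a small sub-flock departs from the
main group. `flockescape` models how both patterns emerge from a single
individual-level rule — a *discrete, stochastic, uncoordinated escape
manoeuvre* — layered on top of ordinary flocking coordination, and
provides the measurement machinery to detect and classify these
patterns in 2-D trajectory data (simulated, or GPS-like tables at 5 Hz).

## Model

Each pigeon-oid coordinates with its **seven closest neighbours**
(topological interaction) within a maximum range through three steering
forces — attraction toward the neighbours' centre of mass, alignment
with their mean heading (the strongest force), and separation from the
single closest neighbour — plus speed control that drags each bird
toward its individual cruise speed (~18 m/s). Steering acts as lateral
acceleration: a force of magnitude *a* turns a bird flying at speed *v*
at angular rate *a/v*. Perception is asynchronous across the flock.

The pred-oid runs a 60 s hunting cycle: *pursuit* (tail-chasing the
flock with a weaving aim), *attack* (charging the closest bird), and
*retreat*. Prey respond two ways:

1. **Continuous avoidance** — a steering force that rotates each bird's
   heading away from the *predator's heading* (not its position),
   decaying exponentially with distance to the predator.
2. **Discrete escape manoeuvre** — at each perception update, bird *i*
   manoeuvres with probability

   p_i = tendency_i · exp(−d_i / d₀),

   where `tendency_i` is an individual baseline and `d_i` the distance
   to the predator. The manoeuvre's turning angle and duration are drawn
   **independently from two gamma distributions**; the signed turn rate
   is their ratio, directed away from the predator's heading. While
   manoeuvring the bird ignores its neighbours and the avoidance force.

## Analysis

Operating purely on positions (headings are recovered from finite
differences, as with GPS data):

* **Turn segmentation** — the flock-centroid trajectory is divided into
  sign-consistent angular-velocity intervals; segments below
  10°/s average angular velocity count as straight flight. Per-flight
  metrics: turns/s, proportion of time turning, degrees turned per second.
* **Split detection** — a bird is split once no main-flock member
  (largest connected group at ≤ 10 m adjacency) is within 10 m of it for
  at least 2 s; simultaneous departures form a single sub-flock event.
* **Initiator traits** — normalized centrality (distance to flock
  centroid over the size-class mean), escape direction (inwards/outwards
  relative to the flock centre), and manoeuvre angular velocity, each
  median-split over the pooled event dataset.
* **Outcome attribution** — each manoeuvre is classified as `split`,
  `collective_turn`, or `none` from what the main flock does inside the
  manoeuvre window.

## Worked example

```python
from flockescape import BatchSpec, SimConfig, run_batch, trait_contrast

spec = BatchSpec(n_cycles=32, flock_sizes=(8, 10, 27, 34), base_seed=5,
                 cfg=SimConfig())
events = run_batch(spec)
print(len(events.manoeuvres), "manoeuvres")
print(events.manoeuvres["outcome"].value_counts().to_dict())
c = trait_contrast(events, "ang_vel")
print(f"chi2={c.chi2:.1f}  p={c.p_value:.4f}")
print(f"split probability, sharp vs slow turns: {c.rel_increase_split:+.1f}%")
```

prints (32 hunting cycles, ~1 s each on one core):

```
331 manoeuvres
{'split': 104, 'collective_turn': 99, 'none': 74, 'excluded': 54}
chi2=9.0  p=0.0027
split probability, sharp vs slow turns: +53.9%
```

meaning: of 331 escape manoeuvres, 104 ended in the initiator (or a
sub-flock) splitting off and 93 in a whole-flock collective turn
(`excluded` marks initiators that were already outside the main flock).
Manoeuvres with above-median angular velocity were substantially more
likely to end in a split than below-median ones — sharp turns are hard
to follow.

There is also a CLI: `flockescape simulate|detect|experiment|fixture`
(each run writes a JSON manifest with the seed and resolved config, so
outputs are bit-reproducible).

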