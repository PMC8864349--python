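"""The pred-oid hunting cycle and the two prey escape rules.

The predator loops through a fixed-length hunting cycle of pursuit
(holding station behind the flock), attack (accelerating towards its
closest prey) and retreat (leaving the flock's vicinity).  Prey respond
in two ways: a continuous steering force away from the predator's
heading line, and a discrete stochastic escape manoeuvre — a sharp,
finite-duration turn during which the bird neither coordinates with
neighbours nor applies the continuous avoidance force.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .agents import PHASES, ManoeuvreStatus, PigeonState, PredatorState
from .config import SimConfig
from .geometry import angle_of, heading_unit, unit, wrap_deg

__all__ = [
    "update_predator",
    "avoidance_force",
    "manoeuvre_probability",
    "sample_manoeuvre",
    "escape_probability",
    "avoidance_vector",
    "phase_durations",
]

_SPEED_RELAX = 2.0  # 1/s, relaxation of predator speed toward its phase speed


def phase_durations(cfg: SimConfig) -> dict[str, float]:
    """Seconds spent in each hunting-cycle phase; they sum to cycle_duration."""
    f = cfg.predator.phase_fractions
    return {phase: frac * cfg.cycle_duration for phase, frac in zip(PHASES, f)}


def _flock_arrays(flock) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(flock, "pos"):           # array-backed Flock
        return flock.pos, flock.heading
    pos = np.array([p.position for p in flock], dtype=float)
    hdg = np.array([p.heading for p in flock], dtype=float)
    return pos, hdg


def update_predator(predator: PredatorState, flock, cfg: SimConfig,
                    dt: float) -> PredatorState:
    """Advance the pred-oid by one time step (mutates and returns it).

    Pursuit tail-chases the flock: the predator aims at the flock
    centroid with a slowly weaving lateral offset (imitating the
    wandering aim of a piloted pursuer) and holds its distance at
    ``pursuit_distance`` by modulating speed.  Attack steers straight
    at the closest prey at attack speed; retreat steers away from the
    centroid until the retreat distance is reached, after which the
    heading is held.  Speed relaxes toward the phase's target speed;
    turning is capped at the predator's turn-rate limit.
    """
    pos, hdg = _flock_arrays(flock)
    if len(pos) == 0:
        raise ValueError("update_predator requires a non-empty flock")
    pp = cfg.predator
    centroid = pos.mean(axis=0)

    if predator.phase == "pursuit":
        elapsed = phase_durations(cfg)["pursuit"] - predator.phase_clock
        mean_dir = unit(heading_unit(hdg).mean(axis=0))
        perp = np.array([-mean_dir[1], mean_dir[0]])
        weave = pp.weave_amplitude * math.sin(2.0 * math.pi * elapsed / pp.weave_period)
        aim = centroid + weave * perp - predator.position
        range_err = float(np.linalg.norm(centroid - predator.position)) - pp.pursuit_distance
        target_speed = float(np.clip(pp.pursuit_speed + pp.station_gain * range_err,
                                     0.6 * pp.pursuit_speed, 1.5 * pp.pursuit_speed))
    elif predator.phase == "attack":
        d = np.linalg.norm(pos - predator.position, axis=1)
        aim = pos[int(np.argmin(d))] - predator.position
        target_speed = pp.attack_speed
    else:  # retreat
        away = predator.position - centroid
        aim = away if np.linalg.norm(away) < pp.retreat_distance else None
        target_speed = pp.retreat_speed

    if aim is not None and np.linalg.norm(aim) > 1e-9:
        dtheta = wrap_deg(angle_of(aim) - predator.heading)
        limit = pp.turn_rate_limit_deg_s * dt
        predator.heading = (predator.heading + float(np.clip(dtheta, -limit, limit))) % 360.0
    predator.speed += _SPEED_RELAX * (target_speed - predator.speed) * dt
    predator.position = predator.position + predator.speed * dt * heading_unit(predator.heading)

    predator.phase_clock -= dt
    if predator.phase_clock <= 1e-9:
        nxt = PHASES[(PHASES.index(predator.phase) + 1) % len(PHASES)]
        predator.phase = nxt
        predator.phase_clock += phase_durations(cfg)[nxt]
    return predator


def avoidance_vector(position: np.ndarray, heading: float,
                     predator: Optional[PredatorState],
                     cfg: SimConfig) -> np.ndarray:
    """Continuous predator-avoidance steering for one bird.

    Real pigeons evade the predator's direction of travel rather than
    its position: the force is a pure lateral steering (perpendicular
    to the bird's own heading) on the side that rotates the bird's
    heading *away from the predator's heading* — the same directional
    rule as the discrete manoeuvre, of which this is the continuous
    counterpart.  Degenerate geometry (headings parallel) breaks the
    tie away from the predator's position, then left.  The magnitude
    decays exponentially with distance to the predator and is zero
    beyond the predator's influence distance or without a predator.
    """
    if predator is None:
        return np.zeros(2)
    pos = np.asarray(position, dtype=float)
    dist = float(np.linalg.norm(pos - predator.position))
    if dist > cfg.predator.influence_distance:
        return np.zeros(2)
    s = manoeuvre_sign(predator.position, predator.heading, pos, heading)
    hu = heading_unit(heading)
    perp = np.array([-hu[1], hu[0]]) * s
    decay = min(math.exp(-dist / cfg.escape_distance_scale), cfg.avoidance_cap)
    return cfg.weight_predator_avoidance * decay * perp


def avoidance_force(focal: PigeonState, predator: Optional[PredatorState],
                    cfg: SimConfig) -> np.ndarray:
    """Continuous avoidance steering for a non-manoeuvring bird."""
    return avoidance_vector(focal.position, focal.heading, predator, cfg)


def escape_probability(dist: float, escape_tendency: float, cfg: SimConfig) -> float:
    """Per-perception-update manoeuvre probability at a given predator distance."""
    p = escape_tendency * math.exp(-dist / cfg.escape_distance_scale)
    return float(min(max(p, 0.0), 1.0))


def manoeuvre_probability(focal: PigeonState, predator: Optional[PredatorState],
                          cfg: SimConfig) -> float:
    """Probability that ``focal`` starts an escape manoeuvre at this update.

    The product of the bird's baseline escape tendency and an
    exponential decay with its distance to the predator: the closer the
    predator, the likelier the manoeuvre.  Zero without a predator.
    """
    if predator is None:
        return 0.0
    dist = float(np.linalg.norm(focal.position - predator.position))
    return escape_probability(dist, focal.escape_tendency, cfg)


def manoeuvre_sign(pred_position: np.ndarray, pred_heading: float,
                   position: np.ndarray, heading: float) -> float:
    """Turn direction (+1 left, -1 right) rotating ``heading`` away from
    the predator's heading; ties (parallel or anti-parallel headings,
    where both turns are equally evasive) break away from the
    predator's position, then left."""

    def side(delta: float) -> float:
        if delta == 0.0 or abs(abs(delta) - 180.0) < 1e-9:
            return 0.0
        return -math.copysign(1.0, delta)

    s = side(wrap_deg(pred_heading - heading))
    if s:
        return s
    towards_pred = np.asarray(pred_position, dtype=float) - np.asarray(position, dtype=float)
    if np.linalg.norm(towards_pred) > 1e-12:
        s = side(wrap_deg(angle_of(towards_pred) - heading))
        if s:
            return s
    return 1.0


def sample_manoeuvre(predator: PredatorState, focal: PigeonState, cfg: SimConfig,
                     rng: np.random.Generator) -> ManoeuvreStatus:
    """Draw one discrete escape manoeuvre.

    Turning angle (degrees) and duration (seconds) are sampled
    independently from two gamma distributions; the signed turn rate is
    their ratio, directed away from the predator's heading.
    """
    angle = float(rng.gamma(cfg.gamma_angle_shape, cfg.gamma_angle_scale))
    duration = float(rng.gamma(cfg.gamma_duration_shape, cfg.gamma_duration_scale))
    angle = max(angle, 1e-6)
    duration = max(duration, 1e-6)
    sign = manoeuvre_sign(predator.position, predator.heading,
                          focal.position, focal.heading)
    return ManoeuvreStatus(
        remaining_duration=duration,
        turn_rate=sign * angle / duration,
        total_angle=angle,
        sampled_duration=duration,
    )


def spawn_predator(flock, cfg: SimConfig) -> PredatorState:
    """A predator starting one pursuit-distance behind the flock, in pursuit."""
    pos, hdg = _flock_arrays(flock)
    centroid = pos.mean(axis=0)
    mean_dir = unit(heading_unit(hdg).mean(axis=0))
    start = centroid - cfg.predator.pursuit_distance * mean_dir
    return PredatorState(
        position=start,
        heading=angle_of(mean_dir) if np.linalg.norm(mean_dir) else 0.0,
        speed=cfg.predator.pursuit_speed,
        phase="pursuit",
        phase_clock=phase_durations(cfg)["pursuit"],
    )
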